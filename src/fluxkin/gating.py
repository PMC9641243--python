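"""FMO-threshold gating into B-cell subsets, prevalence and viability.

CD19+ events are partitioned by the (IgD, CD27) sign pattern — (+,-) naive,
(+,+) non-switched memory, (-,+) switched memory, (-,-) double-negative — and
split by CD25 status.  Positivity is strict (values exactly at a threshold
count as negative).  The indicator-loading gate doubles as the viability
gate: only intact cells hold the calcium dye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flowio import SchemaError

__all__ = [
    "GatingScheme",
    "fmo_threshold",
    "classify_events",
    "prevalence_table",
    "viability_fraction",
    "SUBSET_PATTERNS",
]

#: (IgD positive, CD27 positive) -> subset label over CD19+ events.
SUBSET_PATTERNS = {
    (True, False): "naive",
    (True, True): "NSw",
    (False, True): "Sw",
    (False, False): "DN",
}

#: Default quantile of the FMO control used as the positivity threshold
#: (0.5% of FMO events fall above the cut).
DEFAULT_FMO_QUANTILE = 0.995


@dataclass(frozen=True)
class GatingScheme:
    """Per-channel positivity thresholds plus the indicator-loading threshold."""

    thresholds: dict[str, float]
    loading_threshold: float = 10.0
    scatter_gate: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for ch in ("CD19", "IgD", "CD27", "CD25"):
            if ch not in self.thresholds:
                raise ValueError(f"gating scheme lacks a threshold for {ch}")
            if not np.isfinite(self.thresholds[ch]):
                raise ValueError(f"threshold for {ch} is not finite")
        if not np.isfinite(self.loading_threshold):
            raise ValueError("loading threshold must be finite")

    @classmethod
    def from_fmo(
        cls,
        fmo_values: dict[str, np.ndarray],
        quantile: float = DEFAULT_FMO_QUANTILE,
        loading_threshold: float = 10.0,
    ) -> "GatingScheme":
        """Build a scheme by taking the FMO quantile per channel."""
        thr = {ch: fmo_threshold(v, quantile) for ch, v in fmo_values.items()}
        return cls(thresholds=thr, loading_threshold=loading_threshold)


def fmo_threshold(fmo_values, q: float = DEFAULT_FMO_QUANTILE) -> float:
    """Positivity threshold: the ``q``-quantile of an FMO control distribution."""
    values = np.asarray(fmo_values, dtype=float)
    if values.size == 0:
        raise ValueError("FMO control has no events")
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    return float(np.quantile(values, q))


def _lymphocyte_mask(events: pd.DataFrame, scheme: GatingScheme) -> np.ndarray:
    # without scatter channels the lymphocyte gate is the all-events gate
    mask = np.ones(len(events), dtype=bool)
    if scheme.scatter_gate:
        for ch, (lo, hi) in scheme.scatter_gate.items():
            if ch in events.columns:
                v = events[ch].to_numpy(dtype=float)
                mask &= (v >= lo) & (v <= hi)
    return mask


def classify_events(events: pd.DataFrame, scheme: GatingScheme) -> pd.DataFrame:
    """Per-event subset label, CD25 status and viability flag.

    Returns a frame with columns ``subset`` (naive/NSw/Sw/DN/nonB), ``cd25``
    (bool), ``viable`` (bool, indicator-loading gate) and ``lymphocyte``
    (bool).  Every event receives exactly one subset label.
    """
    required = ("CD19", "IgD", "CD27", "CD25", "Fluo4")
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise SchemaError(f"missing required channel(s): {', '.join(missing)}")

    def positive(ch):
        return events[ch].to_numpy(dtype=float) > scheme.thresholds[ch]

    cd19 = positive("CD19")
    igd = positive("IgD")
    cd27 = positive("CD27")
    cd25 = positive("CD25")

    subset = np.full(len(events), "nonB", dtype=object)
    for (p_igd, p_cd27), label in SUBSET_PATTERNS.items():
        subset[cd19 & (igd == p_igd) & (cd27 == p_cd27)] = label

    viable = events["Fluo4"].to_numpy(dtype=float) > scheme.loading_threshold
    out = pd.DataFrame(
        {
            "subset": subset,
            "cd25": cd25,
            "viable": viable,
            "lymphocyte": _lymphocyte_mask(events, scheme),
        },
        index=events.index,
    )
    out.attrs["sample_id"] = events.attrs.get("sample_id", "")
    return out


def prevalence_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Subset percentages of CD19+ viable B cells, with per-subset CD25+ fractions.

    Returns one row per subset: ``percent`` of B cells and ``cd25_percent``
    within the subset.  Percentages sum to 100 over the four subsets.
    """
    b = labels[(labels["subset"] != "nonB") & labels["viable"] & labels["lymphocyte"]]
    n_b = len(b)
    if n_b == 0:
        raise ValueError("no viable CD19+ events to tabulate")
    rows = []
    for s in ("naive", "NSw", "Sw", "DN"):
        sub = b[b["subset"] == s]
        rows.append(
            {
                "subset": s,
                "count": len(sub),
                "percent": 100.0 * len(sub) / n_b,
                "cd25_percent": (
                    100.0 * sub["cd25"].mean() if len(sub) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def viability_fraction(events: pd.DataFrame, scheme: GatingScheme) -> float:
    """Fraction of lymphocyte-gated events passing the indicator-loading gate."""
    if len(events) == 0:
        raise ValueError("no events")
    labels = classify_events(events, scheme)
    lymph = labels[labels["lymphocyte"]]
    if len(lymph) == 0:
        raise ValueError("no events inside the lymphocyte gate")
    return float(lymph["viable"].mean())
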