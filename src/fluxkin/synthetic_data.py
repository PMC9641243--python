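"""Synthetic kinetic-cytometry event streams and cohorts with known ground truth.

The generator emulates a 17-minute kinetic acquisition: a 2-minute
unstimulated baseline followed by stimulation at 120 s, a mixture of B-cell
subsets with distinct calcium-flux kinetics, log-normal marker and indicator
noise, and a small unloaded (indicator-negative) fraction.  Every stream is a
deterministic function of its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import double_logistic

__all__ = [
    "KineticGroundTruth",
    "SubsetSpec",
    "CohortDesign",
    "GroupSpec",
    "true_curve",
    "generate_event_stream",
    "generate_cohort",
    "default_subset_specs",
    "default_ground_truth",
    "FLUOR_CHANNELS",
    "B_SUBSETS",
]

#: Fluorescence channel roles carried by every synthetic event table.
FLUOR_CHANNELS = ("Fluo4", "CD19", "IgD", "CD27", "CD25", "CD5")

#: CD19+ subset labels by (IgD, CD27) sign pattern.
B_SUBSETS = ("naive", "NSw", "Sw", "DN")

# log-scale locations for "negative" and "positive" marker populations;
# separation is (LOG_POS - LOG_NEG) / MARKER_SD = 11.5 SD, comfortably
# beyond the 6-SD separability assumed by the gating recovery checks.
_LOG_NEG = np.log(10.0)
_LOG_POS = np.log(1000.0)
_MARKER_SD = 0.4

#: Fluo-4 intensity of unloaded (membrane-damaged) cells: near zero.
_UNLOADED_LOG_MEAN = np.log(1.0)
_UNLOADED_LOG_SD = 0.3


@dataclass(frozen=True)
class KineticGroundTruth:
    """True double-logistic coefficients of one subset's calcium flux.

    ``S`` is the pre-stimulus plateau; the rising logistic (``A1``, ``r1``,
    ``tau1``) precedes the falling one (``A2``, ``r2``, ``tau2``), and
    ``A2 <= A1`` so the ending plateau is at or above the starting level.
    """

    S: float
    A1: float = 0.0
    r1: float = 0.05
    tau1: float = 200.0
    A2: float = 0.0
    r2: float = 0.02
    tau2: float = 400.0

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("S must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("rates must be positive")
        if self.A2 > self.A1:
            raise ValueError("A2 must not exceed A1 (ending plateau >= start)")
        if self.A2 > 0 and not self.tau1 < self.tau2:
            raise ValueError("tau1 must precede tau2 when a decay is present")

    @property
    def coefficients(self) -> tuple[float, ...]:
        return (self.S, self.A1, self.r1, self.tau1, self.A2, self.r2, self.tau2)

    def scaled(self, amplitude_multiplier: float) -> "KineticGroundTruth":
        """Ground truth with both amplitudes scaled by a group-effect multiplier."""
        return dataclasses.replace(
            self,
            A1=self.A1 * amplitude_multiplier,
            A2=self.A2 * amplitude_multiplier,
        )


@dataclass(frozen=True)
class SubsetSpec:
    """Mixture component: marker distribution plus kinetic ground truth."""

    label: str
    proportion: float
    marker_means: dict[str, float]
    marker_sds: dict[str, float]
    kinetics: KineticGroundTruth
    loaded_fraction: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must be in [0, 1]")
        if not 0.0 <= self.loaded_fraction <= 1.0:
            raise ValueError("loaded_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort settings."""

    name: str
    n_samples: int
    amplitude_multiplier: float = 1.0
    subject_prefix: str = ""


@dataclass(frozen=True)
class CohortDesign:
    """Full synthetic study design.

    ``pairing`` maps a sample of one group to the subject id shared with its
    counterpart in another group (the pre/post-treatment design); groups
    without pairing get fresh subject ids.
    """

    groups: tuple[GroupSpec, ...]
    events_per_sample: int = 20000
    duration: float = 1020.0
    stim_time: float = 120.0
    seed: int = 0
    subset_specs: tuple[SubsetSpec, ...] | None = None
    noise_sd: float = 0.15
    truth_jitter_sd: float = 0.08
    paired_groups: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.duration < self.stim_time:
            raise ValueError("duration must be >= stimulation time")
        if self.paired_groups is not None:
            names = {g.name for g in self.groups}
            missing = set(self.paired_groups) - names
            if missing:
                raise ValueError(f"paired groups not in design: {sorted(missing)}")


def true_curve(g: KineticGroundTruth, t) -> np.ndarray | float:
    """Noiseless expected fluorescence of ground truth ``g`` at time(s) ``t``."""
    out = double_logistic(np.asarray(t, dtype=float), *g.coefficients)
    return float(out) if np.ndim(t) == 0 else out


def default_ground_truth(label: str) -> KineticGroundTruth:
    """Default per-subset kinetics: distinct rise/decay profiles per subset."""
    table = {
        "naive": KineticGroundTruth(S=100, A1=120, r1=0.06, tau1=180, A2=60, r2=0.015, tau2=420),
        "NSw": KineticGroundTruth(S=110, A1=150, r1=0.05, tau1=200, A2=80, r2=0.012, tau2=480),
        "Sw": KineticGroundTruth(S=95, A1=100, r1=0.07, tau1=170, A2=40, r2=0.018, tau2=380),
        "DN": KineticGroundTruth(S=105, A1=80, r1=0.045, tau1=220, A2=35, r2=0.014, tau2=500),
        "nonB": KineticGroundTruth(S=90),
    }
    return table[label]


def _marker_profile(cd19: bool, igd: bool, cd27: bool, cd25: bool, cd5: bool = False):
    flags = {"CD19": cd19, "IgD": igd, "CD27": cd27, "CD25": cd25, "CD5": cd5}
    means = {ch: (_LOG_POS if on else _LOG_NEG) for ch, on in flags.items()}
    sds = {ch: _MARKER_SD for ch in flags}
    return means, sds


def default_subset_specs(
    proportions: dict[str, float] | None = None,
    cd25_positive_fraction: float = 0.15,
    loaded_fraction: float = 0.98,
    non_b_fraction: float = 0.20,
) -> tuple[SubsetSpec, ...]:
    """Default mixture: four CD19+ subsets split by CD25 status, plus non-B.

    ``proportions`` are fractions of B cells per main subset and default to
    (naive 0.60, NSw 0.20, Sw 0.15, DN 0.05).
    """
    if proportions is None:
        proportions = {"naive": 0.60, "NSw": 0.20, "Sw": 0.15, "DN": 0.05}
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("B-subset proportions must sum to 1")

    sign = {"naive": (True, False), "NSw": (True, True),
            "Sw": (False, True), "DN": (False, False)}
    b_total = 1.0 - non_b_fraction
    specs = []
    for label in B_SUBSETS:
        igd, cd27 = sign[label]
        for cd25 in (False, True):
            frac = cd25_positive_fraction if cd25 else 1.0 - cd25_positive_fraction
            means, sds = _marker_profile(True, igd, cd27, cd25)
            specs.append(
                SubsetSpec(
                    label=f"{label}{'+' if cd25 else '-'}CD25",
                    proportion=b_total * proportions[label] * frac,
                    marker_means=means,
                    marker_sds=sds,
                    kinetics=default_ground_truth(label),
                    loaded_fraction=loaded_fraction,
                )
            )
    means, sds = _marker_profile(False, False, False, False)
    specs.append(
        SubsetSpec(
            label="nonB",
            proportion=non_b_fraction,
            marker_means=means,
            marker_sds=sds,
            kinetics=default_ground_truth("nonB"),
            loaded_fraction=loaded_fraction,
        )
    )
    return tuple(specs)


def main_subset(label: str) -> str:
    """Collapse a spec label like ``naive+CD25`` to its main subset name."""
    for s in B_SUBSETS:
        if label.startswith(s):
            return s
    return "nonB"


def generate_event_stream(
    specs,
    n_events: int,
    duration: float = 1020.0,
    stim_time: float = 120.0,
    seed: int | np.random.SeedSequence = 0,
    noise_sd: float = 0.15,
    sample_id: str = "",
) -> pd.DataFrame:
    """Draw one event table: time, fluorescence channels and ground-truth labels.

    Acquisition times are uniform on ``[0, duration]`` (sorted, as a cytometer
    records them).  Each event's subset is drawn by mixture proportion; marker
    intensities are log-normal around the subset's log-scale locations; the
    Fluo-4 intensity of loaded cells is log-normal with median
    ``true_curve(g, t)`` after stimulation and ``S`` before; unloaded cells
    get near-zero Fluo-4.  The returned frame carries ``true_subset`` and
    ``true_loaded`` columns (ground truth, not measurements).
    """
    specs = list(specs)
    if n_events < 0:
        raise ValueError("n_events must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    props = np.array([s.proportion for s in specs], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError(f"subset proportions sum to {props.sum():.6f}, not 1")

    columns = ["time", *FLUOR_CHANNELS, "true_subset", "true_loaded"]
    if n_events == 0:
        empty = {c: np.array([], dtype=float) for c in columns}
        empty["true_subset"] = np.array([], dtype=object)
        empty["true_loaded"] = np.array([], dtype=bool)
        return pd.DataFrame(empty)

    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, duration, size=n_events))
    which = rng.choice(len(specs), size=n_events, p=props / props.sum())
    loaded = rng.uniform(size=n_events) < np.array(
        [s.loaded_fraction for s in specs]
    )[which]

    data = {"time": t}
    noise = {ch: rng.normal(0.0, 1.0, size=n_events) for ch in FLUOR_CHANNELS}

    for ch in FLUOR_CHANNELS:
        if ch == "Fluo4":
            continue
        mu = np.array([s.marker_means[ch] for s in specs])[which]
        sd = np.array([s.marker_sds[ch] for s in specs])[which]
        data[ch] = np.exp(mu + sd * noise[ch])

    # Fluo-4: median tracks the true curve post-stimulation, flat S before
    fluo_med = np.empty(n_events)
    for i, s in enumerate(specs):
        m = which == i
        if not m.any():
            continue
        tm = t[m]
        vals = np.where(
            tm < stim_time, s.kinetics.S, true_curve(s.kinetics, tm)
        )
        fluo_med[m] = vals
    log_fluo = np.where(
        loaded,
        np.log(fluo_med) + noise_sd * noise["Fluo4"],
        _UNLOADED_LOG_MEAN + _UNLOADED_LOG_SD * noise["Fluo4"],
    )
    data["Fluo4"] = np.exp(log_fluo)
    data["true_subset"] = np.array([specs[i].label for i in which], dtype=object)
    data["true_loaded"] = loaded

    df = pd.DataFrame(data, columns=columns)
    df.attrs["sample_id"] = sample_id
    return df


def _jittered_specs(specs, rng, jitter_sd, amplitude_multiplier):
    """Per-sample biological variability: log-normal jitter on S and amplitudes."""
    out = []
    for s in specs:
        jS, jA = np.exp(rng.normal(0.0, jitter_sd, size=2))
        k = s.kinetics
        jk = dataclasses.replace(
            k,
            S=k.S * jS,
            A1=k.A1 * jA * amplitude_multiplier,
            A2=k.A2 * jA * amplitude_multiplier,
        )
        out.append(dataclasses.replace(s, kinetics=jk))
    return out


def generate_cohort(design: CohortDesign, out_dir: str | Path) -> pd.DataFrame:
    """Write one CSV event table per sample plus a cohort manifest.

    Returns the manifest frame (sample_id, group, subject_id, path, seed and a
    JSON-encoded ground-truth column).  Regeneration with the same design is
    byte-identical.
    """
    from .flowio import write_event_table  # local import to avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = design.subset_specs or default_subset_specs()

    root = np.random.SeedSequence(design.seed)
    records = []
    paired = set(design.paired_groups or ())

    for gi, grp in enumerate(design.groups):
        for si in range(grp.n_samples):
            if grp.name in paired:
                # paired groups index the same subjects
                subject = f"subj{si:03d}"
            else:
                subject = f"{grp.name}_subj{si:03d}"
            sample_id = f"{grp.name}_s{si:03d}"
            ss = np.random.SeedSequence(
                entropy=design.seed, spawn_key=(gi, si)
            )
            rng = np.random.default_rng(ss)
            sample_specs = _jittered_specs(
                specs, rng, design.truth_jitter_sd, grp.amplitude_multiplier
            )
            events = generate_event_stream(
                sample_specs,
                design.events_per_sample,
                duration=design.duration,
                stim_time=design.stim_time,
                seed=rng,
                noise_sd=design.noise_sd,
                sample_id=sample_id,
            )
            path = out_dir / f"{sample_id}.csv"
            write_event_table(events, path)
            truth = {
                s.label: dict(zip(
                    ("S", "A1", "r1", "tau1", "A2", "r2", "tau2"),
                    s.kinetics.coefficients,
                ))
                for s in sample_specs
            }
            records.append(
                {
                    "sample_id": sample_id,
                    "group": grp.name,
                    "subject_id": subject,
                    # stored relative to the manifest so bundles relocate cleanly
                    "path": path.name,
                    "seed": design.seed,
                    "ground_truth": json.dumps(truth, sort_keys=True),
                }
            )

    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
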