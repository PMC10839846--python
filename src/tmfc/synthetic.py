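"""Synthetic cohort generator with planted time-varying modular structure.

Each subject's region x time signal matrix is built from a block model whose
community structure switches at planted epoch boundaries.  Within an epoch,
node i in block b follows

    x_i(t) = a * g(t) + c * f_b(t) + e_i(t)

with iid standard-normal global factor ``g``, block factors ``f_b`` and node
noise ``e_i``.  Choosing ``a^2 = r_b / (1 - r_w)`` and
``c^2 = (r_w - r_b) / (1 - r_w)`` makes the population correlation exactly
``r_w`` for same-block pairs and ``r_b`` for cross-block pairs.  At each
epoch boundary a fixed fraction of nodes moves to a different block, which
plants the switching that flexibility should recover downstream.

Group structure mimics an amyloid-PET-stratified aging cohort: four groups
(CN Ab-, CN Ab+, MCI Ab+, AD Ab+) with additive shifts on the correlation
structure and switch rate, plus demographics (age, sex, APOE e4, education)
and outcome variables (MMSE, ADAS Q4, tau and amyloid SUVR) generated from
the planted dynamic levels through a linear covariate model with noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .community import CommunityEnsemble
from .networks import RegionTimeSeries

GROUPS = ("CN_Abneg", "CN_Abpos", "MCI_Abpos", "AD_Abpos")

#: region counts of the seven systems (sums to 200, limbic smallest)
DEFAULT_RSN_SIZES = (30, 32, 26, 24, 12, 30, 46)


class InvalidDesignError(ValueError):
    """Raised when a simulation design violates its own constraints."""


@dataclass
class GroupEffect:
    """Additive shifts a group applies to the baseline generative parameters."""

    d_within: float = 0.0
    d_between: float = 0.0
    d_switch: float = 0.0


@dataclass
class CovariateModel:
    """Linear map from planted dynamic levels to outcome variables.

    ``coefficients[response]`` maps planted-measure names (``switch_rate``,
    ``between_corr``, ``within_corr``) to slopes; each response also has an
    intercept and a Gaussian noise standard deviation.
    """

    intercepts: dict[str, float] = field(default_factory=dict)
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CovariateModel":
        # slopes chosen so the four groups' expected outcomes span the
        # qualitative ranges of an amyloid-stratified cohort
        return cls(
            intercepts={"MMSE": 29.0, "ADAS_Q4": 2.0, "tau_suvr": 1.75,
                        "amyloid_suvr": 1.00},
            coefficients={
                "MMSE": {"switch_rate": 20.0, "between_corr": -30.0},
                "ADAS_Q4": {"switch_rate": -15.0, "between_corr": 25.0},
                "tau_suvr": {"switch_rate": -1.0, "between_corr": 2.5},
                "amyloid_suvr": {"between_corr": 2.5},
            },
            noise_sd={"MMSE": 1.5, "ADAS_Q4": 1.5, "tau_suvr": 0.25,
                      "amyloid_suvr": 0.10},
        )


@dataclass
class SimulationDesign:
    """Full specification of a synthetic cohort.

    Defaults emulate the acquisition this pipeline targets: 200 regions in
    seven systems, 200 volumes at TR = 3 s with the first two dropped
    downstream, epochs of 60 s aligned to 30-s analysis windows, and four
    groups of 86/37/34/22 subjects.
    """

    n_regions: int = 200
    n_timepoints: int = 200
    tr_s: float = 3.0
    rsn_sizes: tuple[int, ...] = DEFAULT_RSN_SIZES
    group_sizes: tuple[int, ...] = (86, 37, 34, 22)
    group_names: tuple[str, ...] = GROUPS
    within_block_corr: float = 0.6
    between_block_corr: float = 0.1
    switch_fraction: float = 0.2
    epoch_length_s: float = 60.0
    epoch_jitter_s: float = 0.0
    window_len_s: float = 30.0
    factor_alignment: bool = True
    drop_initial: int = 2
    group_effects: dict[str, GroupEffect] = field(default_factory=dict)
    covariate_model: CovariateModel = field(default_factory=CovariateModel.default)
    age_mean: tuple[float, ...] = (75.1, 78.4, 79.6, 82.4)
    age_sd: tuple[float, ...] = (8.0, 7.0, 7.0, 5.0)
    apoe_rate: tuple[float, ...] = (0.2326, 0.4595, 0.5588, 0.5455)
    education_mean: tuple[float, ...] = (18.0, 16.0, 16.0, 16.0)
    education_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.rsn_sizes) != self.n_regions:
            raise InvalidDesignError(
                f"rsn_sizes sums to {sum(self.rsn_sizes)}, expected {self.n_regions}"
            )
        if not (0.0 <= self.between_block_corr < self.within_block_corr < 1.0):
            raise InvalidDesignError(
                "need 0 <= between_block_corr < within_block_corr < 1"
            )
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise InvalidDesignError("switch_fraction must lie in [0, 1]")
        if self.epoch_length_s < 2 * self.tr_s:
            raise InvalidDesignError("epoch_length_s must cover at least 2 samples")
        if not self.group_effects:
            # graded shifts along the disease continuum: more between-block
            # coupling (integration up) and less switching (flexibility down)
            self.group_effects = {
                self.group_names[0]: GroupEffect(),
                self.group_names[1]: GroupEffect(d_between=0.05, d_switch=-0.05),
                self.group_names[2]: GroupEffect(d_between=0.08, d_switch=-0.08),
                self.group_names[3]: GroupEffect(d_between=0.12, d_switch=-0.10),
            }

    @property
    def n_blocks(self) -> int:
        return len(self.rsn_sizes)

    @property
    def epoch_timepoints(self) -> int:
        return int(round(self.epoch_length_s / self.tr_s))

    def base_blocks(self) -> np.ndarray:
        """Block index of each region in epoch 0 (the RSN partition)."""
        return np.repeat(np.arange(self.n_blocks), self.rsn_sizes)

    def epoch_of_timepoint(self, offset_tp: int = 0) -> np.ndarray:
        """Epoch index of every timepoint (leading/trailing margins absorbed).

        ``offset_tp`` shifts the epoch grid forward (per-subject jitter);
        the default grid is aligned to the analysis-window boundaries.
        """
        tp = np.arange(self.n_timepoints)
        rel = np.maximum(tp - self.drop_initial - offset_tp, 0)
        usable = self.n_timepoints - self.drop_initial - offset_tp
        n_epochs = max(usable // self.epoch_timepoints, 1)
        return np.minimum(rel // self.epoch_timepoints, n_epochs - 1)


@dataclass
class SubjectTruth:
    """Planted ground truth for one subject."""

    epoch_boundaries: np.ndarray          # first timepoint of each epoch
    block_labels: np.ndarray              # n_regions x n_epochs
    switch_rate: float                    # realized fraction of boundary changes
    within_corr: float
    between_corr: float
    n_timepoints: int
    tr_s: float
    drop_initial: int

    @property
    def n_epochs(self) -> int:
        return self.block_labels.shape[1]


@dataclass
class CohortTruth:
    """Ground truth for a whole cohort plus the generating covariate model."""

    subjects: list[SubjectTruth]
    groups: list[str]
    covariate_model: CovariateModel


def _effective_params(design: SimulationDesign, group: str) -> tuple[float, float, float]:
    eff = design.group_effects.get(group, GroupEffect())
    within = float(np.clip(design.within_block_corr + eff.d_within, 1e-6, 0.999))
    between = float(np.clip(design.between_block_corr + eff.d_between, 0.0, within - 1e-6))
    switch = float(np.clip(design.switch_fraction + eff.d_switch, 0.0, 1.0))
    return within, between, switch


def _plant_blocks(
    design: SimulationDesign, switch: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    jitter_tp = int(round(design.epoch_jitter_s / design.tr_s))
    offset = int(rng.integers(0, jitter_tp + 1)) if jitter_tp > 0 else 0
    epoch_of_t = design.epoch_of_timepoint(offset)
    n_epochs = int(epoch_of_t.max()) + 1
    boundaries = np.array(
        [int(np.flatnonzero(epoch_of_t == e)[0]) for e in range(n_epochs)]
    )
    # excursion model: the RSN template is the stable backbone; each epoch a
    # fraction of nodes is displaced to another block and reverts afterwards
    # unless re-selected, as in the RSN-anchored allegiance structure of
    # resting-state data
    base = design.base_blocks()
    labels = np.empty((design.n_regions, n_epochs), dtype=int)
    labels[:, 0] = base
    n_switch = int(round(switch * design.n_regions))
    for e in range(1, n_epochs):
        labels[:, e] = base
        movers = rng.choice(design.n_regions, size=n_switch, replace=False)
        for i in movers:
            choices = np.delete(np.arange(design.n_blocks), base[i])
            labels[i, e] = rng.choice(choices)
    if n_epochs > 1:
        realized = float((labels[:, 1:] != labels[:, :-1]).mean())
    else:
        realized = 0.0
    return boundaries, labels, realized, epoch_of_t


def _window_segments(design: SimulationDesign) -> list[tuple[int, int]]:
    """Timepoint segments bounded by analysis-window edges.

    Segments coincide exactly with the analysis windows; the leading dropped
    volumes and any trailing remainder enter no correlation window and are
    left out (they keep raw factor draws).
    """
    wtp = int(round(design.window_len_s / design.tr_s))
    n_windows = (design.n_timepoints - design.drop_initial) // wtp
    return [
        (design.drop_initial + w * wtp, design.drop_initial + (w + 1) * wtp)
        for w in range(n_windows)
    ]


def _draw_factors(
    design: SimulationDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Global and per-block factor realizations.

    With ``factor_alignment`` (the default), the global factor and the block
    factors are made exactly orthogonal, centered, and equal-norm within
    each analysis-window segment.  A handful of factor time courses realized
    over only ~10 samples would otherwise carry sample correlations of order
    1/sqrt(window length) that are shared by every node pair across a block
    pair, swamping the planted structure at the windowed-correlation stage;
    orthogonalization pins the realized factor correlations at their
    population value of zero while leaving node-level noise untouched.
    """
    T, nb = design.n_timepoints, design.n_blocks
    raw_g = rng.standard_normal(T)
    raw_f = rng.standard_normal((nb, T))
    if not design.factor_alignment:
        return raw_g, raw_f
    g = raw_g.copy()
    f = raw_f.copy()
    for lo, hi in _window_segments(design):
        m = hi - lo
        if m < nb + 3:  # not enough centered dimensions to orthogonalize
            g[lo:hi] = raw_g[lo:hi]
            f[:, lo:hi] = raw_f[:, lo:hi]
            continue
        block = np.vstack([raw_g[lo:hi], raw_f[:, lo:hi]])
        block = block - block.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(block.T)          # columns orthonormal, still centered
        q *= np.sqrt(m)                       # unit sample variance
        g[lo:hi] = q[:, 0]
        f[:, lo:hi] = q[:, 1:].T
    return g, f


def generate_subject(
    design: SimulationDesign,
    subject_seed: int,
    group: str | None = None,
) -> tuple[RegionTimeSeries, SubjectTruth]:
    """Generate one subject's signals and the planted truth behind them."""
    group = group or design.group_names[0]
    within, between, switch = _effective_params(design, group)
    rng = np.random.default_rng(subject_seed)
    boundaries, labels, realized, epoch_of_t = _plant_blocks(design, switch, rng)
    a = np.sqrt(between / (1.0 - within))
    c = np.sqrt((within - between) / (1.0 - within))
    T, n = design.n_timepoints, design.n_regions
    g, f = _draw_factors(design, rng)
    e = rng.standard_normal((n, T))
    block_of_t = labels[:, epoch_of_t]            # n x T
    x = a * g[None, :] + c * f[block_of_t, np.arange(T)[None, :]] + e
    ts = RegionTimeSeries(values=x, tr_s=design.tr_s)
    truth = SubjectTruth(
        epoch_boundaries=boundaries, block_labels=labels, switch_rate=realized,
        within_corr=within, between_corr=between, n_timepoints=T,
        tr_s=design.tr_s, drop_initial=design.drop_initial,
    )
    return ts, truth


def _demographics(
    design: SimulationDesign, group_idx: int, rng: np.random.Generator
) -> dict[str, float]:
    age = float(np.clip(rng.normal(design.age_mean[group_idx], design.age_sd[group_idx]), 55, 95))
    return {
        "age": age,
        "sex": int(rng.integers(0, 2)),
        "apoe4": int(rng.random() < design.apoe_rate[group_idx]),
        "education": float(np.clip(rng.normal(design.education_mean[group_idx],
                                              design.education_sd), 6, 24)),
    }


def _outcomes(
    model: CovariateModel, planted: dict[str, float], rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for resp, coefs in model.coefficients.items():
        value = model.intercepts.get(resp, 0.0)
        for name, slope in coefs.items():
            value += slope * planted[name]
        sd = model.noise_sd.get(resp, 0.0)
        if sd > 0:
            value += rng.normal(0.0, sd)
        out[resp] = float(value)
    return out


def generate_cohort(
    design: SimulationDesign,
) -> tuple[list[RegionTimeSeries], pd.DataFrame, CohortTruth]:
    """Generate the full cohort: signals, cohort table, and ground truth.

    All randomness flows from ``design.seed`` through spawned per-subject
    seed sequences, so the cohort is bit-reproducible.
    """
    if len(design.group_sizes) != 4:
        raise InvalidDesignError("group_sizes must have 4 entries")
    if any(g < 2 for g in design.group_sizes):
        raise InvalidDesignError("every group needs at least 2 subjects")
    n_subjects = sum(design.group_sizes)
    seeds = np.random.SeedSequence(design.seed).generate_state(2 * n_subjects)
    series: list[RegionTimeSeries] = []
    truths: list[SubjectTruth] = []
    rows = []
    groups: list[str] = []
    idx = 0
    for gi, (gname, gsize) in enumerate(zip(design.group_names, design.group_sizes)):
        for _ in range(gsize):
            subject_seed = int(seeds[2 * idx]) % (2**31)
            demo_rng = np.random.default_rng(int(seeds[2 * idx + 1]) % (2**31))
            ts, truth = generate_subject(design, subject_seed, group=gname)
            planted = {
                "switch_rate": truth.switch_rate,
                "between_corr": truth.between_corr,
                "within_corr": truth.within_corr,
            }
            row = {"subject_id": f"sub-{idx:04d}", "group": gname}
            row.update(_demographics(design, gi, demo_rng))
            row.update(_outcomes(design.covariate_model, planted, demo_rng))
            rows.append(row)
            series.append(ts)
            truths.append(truth)
            groups.append(gname)
            idx += 1
    cohort = pd.DataFrame(rows)
    return series, cohort, CohortTruth(
        subjects=truths, groups=groups, covariate_model=design.covariate_model
    )


def planted_layer_labels(
    truth: SubjectTruth, window_timepoints: int, drop_initial: int | None = None
) -> np.ndarray:
    """Planted block label per node per analysis window (window-midpoint epoch)."""
    drop = truth.drop_initial if drop_initial is None else drop_initial
    n_windows = (truth.n_timepoints - drop) // window_timepoints
    epoch_starts = truth.epoch_boundaries
    out = np.empty((truth.block_labels.shape[0], n_windows), dtype=int)
    for w in range(n_windows):
        mid = drop + w * window_timepoints + window_timepoints // 2
        epoch = int(np.searchsorted(epoch_starts, mid, side="right") - 1)
        epoch = max(epoch, 0)
        out[:, w] = truth.block_labels[:, min(epoch, truth.n_epochs - 1)]
    return out


def planted_recovery_report(
    truth: SubjectTruth,
    ensemble: CommunityEnsemble,
    window_timepoints: int,
    drop_initial: int | None = None,
) -> np.ndarray:
    """Per-layer NMI between planted blocks and detected communities.

    Normalized mutual information (arithmetic normalization) is averaged
    over the ensemble's repetitions; 1 means exact recovery up to
    relabeling, 0 means no information.
    """
    planted = planted_layer_labels(truth, window_timepoints, drop_initial)
    if planted.shape[0] != ensemble.n_nodes:
        raise ValueError("truth and ensemble disagree on node count")
    if planted.shape[1] != ensemble.n_layers:
        raise ValueError(
            f"truth implies {planted.shape[1]} layers, ensemble has {ensemble.n_layers}"
        )
    scores = np.zeros(ensemble.n_layers)
    for a in ensemble.assignments:
        for s in range(ensemble.n_layers):
            scores[s] += normalized_mutual_info_score(planted[:, s], a.labels[:, s])
    return scores / len(ensemble.assignments)


# ---------------------------------------------------------------------------
# on-disk cohort format

def write_cohort(
    out_dir: str | Path,
    series: list[RegionTimeSeries],
    cohort: pd.DataFrame,
    truth: CohortTruth,
    rsn_labels: np.ndarray,
) -> None:
    """Write per-subject matrices, the cohort CSV, RSN map, and truth JSON."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for sid, ts in zip(cohort["subject_id"], series):
        np.savetxt(out / "timeseries" / f"{sid}.csv", ts.values, delimiter=",")
    cohort.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(
        {"region_index": np.arange(len(rsn_labels)), "rsn_label": rsn_labels}
    ).to_csv(out / "rsn_map.csv", index=False)
    payload = {
        "covariate_model": asdict(truth.covariate_model),
        "groups": truth.groups,
        "subjects": [
            {
                "epoch_boundaries": t.epoch_boundaries.tolist(),
                "block_labels": t.block_labels.tolist(),
                "switch_rate": t.switch_rate,
                "within_corr": t.within_corr,
                "between_corr": t.between_corr,
                "n_timepoints": t.n_timepoints,
                "tr_s": t.tr_s,
                "drop_initial": t.drop_initial,
            }
            for t in truth.subjects
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
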