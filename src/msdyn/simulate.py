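"""Synthetic resting-state EEG cohort with known microstate structure.

The generator emulates the study conditions the analysis assumes: 5-min
eyes-closed 30-channel recordings at 500 Hz in which four quasi-stable
topographies alternate as a semi-Markov process (gamma-distributed stable
periods, mean ~100 ms), modulated by a rectified alpha-band envelope and
buried in spatially white sensor noise. A cohort of 21 high-pain (HP) and
45 low-pain (LP) subjects carries a planted group effect: HP transition
matrices are biased toward class C so that the standardized group
difference in MS-C occurrence equals a configured effect size, and pain
ratings (NRS 0-10) are rank-linked to each subject's true C coverage.

Everything is seeded and bit-reproducible: one ``SimConfig`` plus one seed
determines the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .microstates import (
    CLASS_NAMES,
    LabelSequence,
    MetricsRecord,
    TemplateSet,
    compute_metrics,
    metrics_table,
)
from .montage import Montage, standard_montage
from .recording import Recording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_canonical_templates",
    "sample_state_sequence",
    "render_eeg",
    "simulate_cohort",
]

_C_INDEX = 2  # class C in A,B,C,D order


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Durations are gamma-distributed with subject-level mean jitter; the
    off-diagonal transition matrix is uniform, multiplicatively biased
    toward class C in the HP group. ``snr`` is the amplitude ratio
    RMS(signal)/RMS(noise); ``np.inf`` disables noise.
    """

    n_classes: int = 4
    mean_duration_ms: float = 100.0
    duration_shape: float = 4.0
    subject_duration_sd_ms: float = 10.0
    transition: np.ndarray | None = None  # row-stochastic, zero diagonal
    carrier_hz: float = 10.0
    envelope_floor: float = 0.3
    snr: float = 5.0
    duration_s: float = 300.0
    sfreq: float = 500.0
    n_high: int = 21
    n_low: int = 45
    effect_d: float = 0.88
    bias_sd: float = 0.33
    nrs_link_noise: float = 1.5
    nrs_high: tuple = ((4, 5, 6, 7, 8, 9, 10), (0.30, 0.25, 0.18, 0.12, 0.08, 0.05, 0.02))
    nrs_low: tuple = ((0, 1, 2, 3), (0.35, 0.30, 0.20, 0.15))
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.mean_duration_ms <= 0 or self.duration_shape <= 0:
            raise ValueError("durations must be positive")
        if not self.snr > 0:
            raise ValueError("SNR must be positive")
        if self.duration_s <= 0 or self.sfreq <= 0:
            raise ValueError("recording length and sampling rate must be positive")
        if self.n_high < 0 or self.n_low < 0 or self.n_high + self.n_low == 0:
            raise ValueError("cohort size must be positive")
        if self.envelope_floor <= 0:
            raise ValueError("envelope floor must be > 0")
        if self.transition is not None:
            _check_transition(np.asarray(self.transition), self.n_classes)

    def base_transition(self) -> np.ndarray:
        if self.transition is not None:
            return np.asarray(self.transition, dtype=float)
        return _uniform_transition(self.n_classes)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sfreq))


def _uniform_transition(k: int) -> np.ndarray:
    if k == 1:
        return np.ones((1, 1))
    P = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(P, 0.0)
    return P


def _check_transition(P: np.ndarray, k: int) -> None:
    if P.shape != (k, k):
        raise ValueError("transition matrix has wrong shape")
    if k > 1 and not np.allclose(np.diag(P), 0.0):
        raise ValueError("transition matrix must have zero diagonal")
    if not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition rows must sum to 1")
    if np.any(P < 0):
        raise ValueError("transition probabilities must be nonnegative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    labels: np.ndarray  # (n_subjects, n_samples) int8, true class per sample
    transition_matrices: np.ndarray  # (n_subjects, K, K)
    templates: TemplateSet  # planted maps
    metrics: pd.DataFrame  # true per-subject temporal metrics
    bias: np.ndarray  # per-subject log-bias toward class C
    mean_duration_ms: np.ndarray  # per-subject duration mean
    subject_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# canonical templates


def make_canonical_templates(montage: Montage | None = None) -> TemplateSet:
    """Four canonical scalp maps on the given montage.

    A: left-posterior / right-anterior diagonal gradient; B: the mirrored
    diagonal; C: anterior-posterior gradient with a broad posterior
    emphasis; D: fronto-central extremum. Each map is zero-mean and
    unit-norm across channels; pairwise absolute spatial correlation stays
    below 0.7 so the classes are identifiable.
    """
    if montage is None:
        montage = standard_montage()
    if montage.n_channels < 8:
        raise ValueError("template construction requires at least 8 channels")
    x, y = montage.pos[:, 0], montage.pos[:, 1]
    raw = np.stack(
        [
            (x + y) / np.sqrt(2.0),
            (y - x) / np.sqrt(2.0),
            y + 0.8 * (x**2 + y**2),
            np.exp(-(x**2 + (y - 0.2) ** 2) / 0.35),
        ]
    )
    raw -= raw.mean(axis=1, keepdims=True)
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    return TemplateSet(maps=raw, labels=CLASS_NAMES, provenance="canonical")


# ---------------------------------------------------------------------------
# state sequences


def _sample_runs_batch(
    rng: np.random.Generator,
    P: np.ndarray,
    mean_dur_samples: np.ndarray,
    shape: float,
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized semi-Markov run sampling for a batch of subjects.

    ``P`` is (n_subj, K, K); ``mean_dur_samples`` per subject. Returns
    (run_states, run_lengths) as (n_subj, n_runs_max) arrays; cumulative
    lengths are guaranteed to reach ``n_samples`` for every subject.
    """
    n_subj, k, _ = P.shape
    margin = 1.3
    n_runs = int(np.ceil(n_samples / mean_dur_samples.min() * margin)) + 30
    cum = np.cumsum(P, axis=2)

    while True:
        scale = mean_dur_samples / shape
        lengths = rng.gamma(shape, 1.0, size=(n_subj, n_runs)) * scale[:, None]
        lengths = np.maximum(np.rint(lengths).astype(np.int64), 1)
        states = np.zeros((n_subj, n_runs), dtype=np.int64)
        states[:, 0] = rng.integers(0, k, size=n_subj)
        if k > 1:
            u = rng.uniform(size=(n_subj, n_runs - 1))
            rows = np.arange(n_subj)
            for t in range(1, n_runs):
                c = cum[rows, states[:, t - 1]]  # (n_subj, k)
                states[:, t] = (u[:, t - 1, None] > c).sum(axis=1)
        if np.all(lengths.sum(axis=1) >= n_samples):
            return states, lengths
        n_runs = int(n_runs * 1.5) + 10  # extremely rare at the used margins


def _runs_to_labels(states: np.ndarray, lengths: np.ndarray, n_samples: int) -> np.ndarray:
    lab = np.repeat(states, lengths)[:n_samples]
    return lab.astype(np.int8)


def sample_state_sequence(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    transition: np.ndarray | None = None,
    mean_duration_ms: float | None = None,
) -> np.ndarray:
    """Draw one per-sample microstate label vector (values 0..K-1).

    Run lengths follow the gamma duration law (discretized to samples,
    minimum one sample); successor states follow the off-diagonal
    transition matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    P = np.asarray(transition, dtype=float) if transition is not None else config.base_transition()
    _check_transition(P, config.n_classes)
    mu = mean_duration_ms if mean_duration_ms is not None else config.mean_duration_ms
    mu_samples = np.array([mu * config.sfreq / 1000.0])
    states, lengths = _sample_runs_batch(
        rng, P[None], mu_samples, config.duration_shape, config.n_samples
    )
    return _runs_to_labels(states[0], lengths[0], config.n_samples)


# ---------------------------------------------------------------------------
# EEG rendering


def render_eeg(
    labels: np.ndarray,
    templates: TemplateSet,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "",
    montage: Montage | None = None,
    return_components: bool = False,
):
    """Turn a label sequence into a multichannel recording.

    signal(t) = polarity(run) * envelope(t) * template[label(t)], with a
    strictly positive envelope (floor plus rectified carrier) so every
    sample carries its topography, and a random +/-1 polarity per stable
    run. The polarity factor mimics the alternating oscillation sign of
    real EEG (topographies are polarity-ambiguous by construction) and
    keeps the signal free of a DC topography, so AC-coupled filtering
    leaves the maps intact. White sensor noise is scaled so the realized
    amplitude ratio RMS(signal)/RMS(noise) equals ``config.snr`` exactly.
    """
    labels = np.asarray(labels)
    if templates.k < labels.max() + 1:
        raise ValueError("labels and templates disagree on the number of classes")
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n = labels.size
    t = np.arange(n) / config.sfreq
    phase = rng.uniform(0.0, 2.0 * np.pi)
    envelope = config.envelope_floor + np.abs(
        np.sin(2.0 * np.pi * config.carrier_hz * t + phase)
    )
    # random polarity per run: real scalp oscillations flip sign, which is
    # why the whole analysis disregards polarity
    starts = np.r_[0, np.flatnonzero(np.diff(labels)) + 1]
    run_signs = rng.choice([-1.0, 1.0], size=starts.size)
    signs = np.repeat(run_signs, np.diff(np.r_[starts, n]))
    signal = (envelope * signs) * templates.maps[labels].T  # (C, n)
    if np.isinf(config.snr):
        data = signal
        noise = np.zeros_like(signal)
    else:
        noise = rng.standard_normal(signal.shape)
        sig_rms = np.sqrt(np.mean(signal**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        if sig_rms > 0 and noise_rms > 0:
            noise *= sig_rms / (config.snr * noise_rms)
        data = signal + noise
    rec = Recording(
        data=data,
        sfreq=config.sfreq,
        ch_names=list(montage.ch_names) if montage else [f"ch{i}" for i in range(signal.shape[0])],
        subject_id=subject_id,
        montage=montage,
    )
    if return_components:
        return rec, signal, noise
    return rec


# ---------------------------------------------------------------------------
# planted-effect calibration


def _stationary_c_share(bias: np.ndarray) -> np.ndarray:
    """Embedded-chain stationary probability of class C when every entry
    into C is multiplied by w = exp(bias) and rows renormalized:
    pi_C = w / (2 w + 2) (uniform base, K = 4)."""
    w = np.exp(bias)
    return w / (2.0 * w + 2.0)


def solve_transition_bias(config: SimConfig) -> float:
    """Mean HP log-bias beta such that the planted standardized group
    difference in MS-C occurrence equals ``config.effect_d``.

    Occurrence_C of a subject with bias b and duration mean mu is
    pi_C(b) / mu; group moments are taken over the subject-level
    distributions b ~ N(beta, bias_sd) (HP) or N(0, bias_sd) (LP) and
    mu ~ N(mean_duration, duration_sd) by Gauss-Hermite quadrature, and
    beta is solved with Brent's method. Deterministic, no sampling.
    """
    if config.effect_d == 0.0:
        return 0.0
    nodes, wts = np.polynomial.hermite_e.hermegauss(41)
    wts = wts / wts.sum()
    mu = config.mean_duration_ms / 1000.0 + config.subject_duration_sd_ms / 1000.0 * nodes
    e_inv = float(wts @ (1.0 / mu))
    e_inv2 = float(wts @ (1.0 / mu**2))

    def moments(bmean: float) -> tuple[float, float]:
        q = _stationary_c_share(bmean + config.bias_sd * nodes)
        eq = float(wts @ q)
        eq2 = float(wts @ q**2)
        m = eq * e_inv
        return m, eq2 * e_inv2 - m * m

    n1, n2 = config.n_high, config.n_low
    m0, v0 = moments(0.0)

    w1, w2 = max(n1 - 1, 1), max(n2 - 1, 1)  # degenerate tiny cohorts

    def gap(beta: float) -> float:
        m1, v1 = moments(beta)
        sp = np.sqrt((w1 * v1 + w2 * v0) / (w1 + w2))
        return (m1 - m0) / sp - config.effect_d

    return float(brentq(gap, 0.0, 3.0, xtol=1e-10))


def _biased_transition(base: np.ndarray, bias: float) -> np.ndarray:
    """Multiply entries into class C by exp(bias) and renormalize rows."""
    P = base.copy()
    P[:, _C_INDEX] *= np.exp(bias)
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# cohort


def _draw_covariates(rng: np.random.Generator, group: str, n: int) -> pd.DataFrame:
    """Clinical covariates drawn to match the study's group margins."""
    hp = group == "HP"
    age = rng.normal(52.7 if hp else 54.5, 9.9 if hp else 8.4, n)
    bmi = rng.normal(24.7 if hp else 24.2, 3.8 if hp else 2.9, n).clip(18, 32)
    edu = rng.normal(10.9 if hp else 11.0, 2.6 if hp else 2.8, n).clip(0, None)
    bdi = np.rint(rng.normal(5.3 if hp else 3.3, 4.3 if hp else 2.3, n)).clip(0, None)
    asa1 = rng.uniform(size=n) < (6 / 21 if hp else 16 / 45)
    mastectomy = rng.uniform(size=n) < (11 / 21 if hp else 12 / 45)
    alnd = rng.uniform(size=n) < (14 / 21 if hp else 15 / 45)
    chemo_pre = rng.uniform(size=n) < (9 / 21 if hp else 13 / 45)
    chemo_post = rng.uniform(size=n) < (11 / 21 if hp else 18 / 45)
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "education": np.round(edu, 1),
            "bdi_ii": bdi.astype(int),
            "asa": np.where(asa1, "I", "II"),
            "surgery": np.where(mastectomy, "mastectomy", "breast-conserving"),
            "alnd": np.where(alnd, "Y", "N"),
            "chemo_pre": np.where(chemo_pre, "Y", "N"),
            "chemo_post": np.where(chemo_post, "Y", "N"),
        }
    )


def _rank_linked_nrs(
    rng: np.random.Generator,
    coverage: np.ndarray,
    values: np.ndarray,
    probs: np.ndarray,
    link_noise: float,
) -> np.ndarray:
    """Integer NRS draws assigned to subjects by rank of noisy coverage.

    ``link_noise`` scales rank-breaking noise relative to the within-group
    coverage SD; 0 gives perfect within-group rank matching.
    """
    n = coverage.size
    drawn = np.sort(rng.choice(values, size=n, p=probs))
    sd = coverage.std()
    z = coverage + rng.normal(0.0, link_noise * sd if sd > 0 else 0.0, n)
    out = np.empty(n, dtype=int)
    out[np.argsort(z, kind="stable")] = drawn
    return out


def simulate_cohort(
    config: SimConfig,
    render: bool = True,
) -> tuple[list[Recording], pd.DataFrame, GroundTruth]:
    """Generate the full synthetic cohort.

    Returns (recordings, metadata table, ground truth). With
    ``render=False`` the EEG rendering step is skipped (empty recording
    list) and only state sequences, true metrics, and metadata are
    produced — useful for large Monte-Carlo designs where only the
    generative truth matters.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_subjects = root.spawn(2)
    rng = np.random.default_rng(ss_cohort)

    montage = standard_montage()
    templates = make_canonical_templates(montage)
    n1, n2 = config.n_high, config.n_low
    n = n1 + n2
    groups = np.array(["HP"] * n1 + ["LP"] * n2)
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    beta = solve_transition_bias(config)
    bias = np.r_[
        rng.normal(beta, config.bias_sd, n1),
        rng.normal(0.0, config.bias_sd, n2),
    ]
    mean_dur = rng.normal(
        config.mean_duration_ms, config.subject_duration_sd_ms, n
    ).clip(4000.0 / config.sfreq, None)  # keep at least ~2 samples per run

    base = config.base_transition()
    if config.n_classes == 4:
        P = np.stack([_biased_transition(base, b) for b in bias])
    else:
        P = np.tile(base, (n, 1, 1))

    states, lengths = _sample_runs_batch(
        rng, P, mean_dur * config.sfreq / 1000.0,
        config.duration_shape, config.n_samples,
    )
    labels = np.stack(
        [_runs_to_labels(states[i], lengths[i], config.n_samples) for i in range(n)]
    )

    true_records: list[MetricsRecord] = []
    for i in range(n):
        seq = LabelSequence(
            labels=labels[i].astype(np.int64), sfreq=config.sfreq,
            class_names=CLASS_NAMES[: config.n_classes] if config.n_classes <= 4
            else tuple(str(c) for c in range(config.n_classes)),
            subject_id=subject_ids[i],
        )
        true_records.append(compute_metrics(seq, k=config.n_classes))
    true_metrics = metrics_table(true_records)

    # NRS rank-linked to true C coverage within each group
    cov_c = true_metrics["cov_C"].to_numpy() if "cov_C" in true_metrics else np.zeros(n)
    nrs = np.empty(n, dtype=int)
    nrs[:n1] = _rank_linked_nrs(
        rng, cov_c[:n1], np.array(config.nrs_high[0]),
        np.array(config.nrs_high[1]), config.nrs_link_noise,
    )
    nrs[n1:] = _rank_linked_nrs(
        rng, cov_c[n1:], np.array(config.nrs_low[0]),
        np.array(config.nrs_low[1]), config.nrs_link_noise,
    )

    meta = pd.concat(
        [_draw_covariates(rng, "HP", n1), _draw_covariates(rng, "LP", n2)],
        ignore_index=True,
    )
    meta.insert(0, "subject", subject_ids)
    meta.insert(1, "group", groups)
    meta.insert(2, "nrs", nrs)

    recordings: list[Recording] = []
    if render:
        child_rngs = [np.random.default_rng(s) for s in ss_subjects.spawn(n)]
        for i in range(n):
            rec = render_eeg(
                labels[i], templates, config, rng=child_rngs[i],
                subject_id=subject_ids[i], montage=montage,
            )
            recordings.append(rec)

    truth = GroundTruth(
        labels=labels,
        transition_matrices=P,
        templates=templates,
        metrics=true_metrics,
        bias=bias,
        mean_duration_ms=mean_dur,
        subject_ids=subject_ids,
    )
    return recordings, meta, truth
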