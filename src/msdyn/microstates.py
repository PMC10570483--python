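"""Polarity-invariant microstate segmentation and temporal metrics.

The segmentation follows the standard two-level scheme: per subject, scalp
topographies are sampled at peaks of the global field power (GFP) and
clustered with a modified k-means that treats a map and its sign-flipped
copy as identical; individual template sets are then pooled and clustered
again to yield group templates labeled A-D by matching against canonical
maps. Group templates are fitted back to every sample of every recording,
and duration / occurrence / coverage / transition statistics are computed
from the resulting label sequence.

Conventions
-----------
* Maps are vectors over scalp channels; before any correlation they are
  mean-centered across channels (average reference makes this a no-op).
* Spatial similarity is the absolute Pearson correlation across channels.
* Sample intervals are half-open and 0-based; masked (bad-segment) samples
  never contribute peaks, labels, runs, or transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment

from .recording import Recording

__all__ = [
    "GFPSeries",
    "TemplateSet",
    "LabelSequence",
    "MetricsRecord",
    "CLASS_NAMES",
    "TRANSITION_PAIRS",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_similarity",
    "modified_kmeans",
    "gev",
    "cv_criterion",
    "cluster_individual",
    "cluster_group",
    "backfit",
    "compute_metrics",
    "metrics_table",
]

CLASS_NAMES = ("A", "B", "C", "D")
#: the 12 ordered off-diagonal class pairs, row-major (AB, AC, AD, BA, ...)
TRANSITION_PAIRS = tuple(
    (i, j) for i in range(4) for j in range(4) if i != j
)


# ---------------------------------------------------------------------------
# containers


@dataclass
class GFPSeries:
    """Global field power over time, with detected/excluded peaks."""

    values: np.ndarray
    sfreq: float
    peaks: np.ndarray | None = None
    excluded: np.ndarray | None = None

    def accepted_peaks(self) -> np.ndarray:
        if self.peaks is None:
            raise ValueError("peaks not yet detected; call find_gfp_peaks")
        if self.excluded is None or len(self.excluded) == 0:
            return self.peaks
        return np.setdiff1d(self.peaks, self.excluded)


@dataclass
class TemplateSet:
    """K unit-norm, zero-mean scalp maps plus fit diagnostics.

    ``maps`` has shape (K, n_channels). ``labels`` is None for unlabeled
    individual-level sets and a tuple like ("A","B","C","D") after group-
    level canonical assignment.
    """

    maps: np.ndarray
    labels: tuple[str, ...] | None = None
    gev: float = float("nan")
    cv: float = float("nan")
    provenance: str = ""
    restarts: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (K, n_channels)")
        if self.labels is not None:
            if len(self.labels) != self.k:
                raise ValueError("one label per map required")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("labels must be unique")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def reorder(self, order: np.ndarray, labels: tuple[str, ...]) -> "TemplateSet":
        return TemplateSet(self.maps[order], labels, self.gev, self.cv,
                           self.provenance, self.restarts)


@dataclass
class LabelSequence:
    """Per-sample microstate labels aligned to a recording.

    ``labels`` holds class indices (0..K-1) with -1 for masked samples;
    ``correlation`` is the fitted absolute spatial correlation (NaN where
    masked).
    """

    labels: np.ndarray
    sfreq: float
    correlation: np.ndarray | None = None
    class_names: tuple[str, ...] = CLASS_NAMES
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    def mask(self) -> np.ndarray:
        return self.labels >= 0


@dataclass
class MetricsRecord:
    """Per-subject temporal microstate statistics.

    duration: mean run length per class (ms); occurrence: runs per second
    of unmasked data; coverage: percent of unmasked samples; transitions:
    percent of all observed label changes going i -> j, for the 12 ordered
    off-diagonal pairs.
    """

    subject_id: str
    duration_ms: dict[str, float]
    occurrence_hz: dict[str, float]
    coverage_pct: dict[str, float]
    transition_pct: dict[str, float]
    n_transitions: int = 0
    warning: str | None = None

    def to_series(self) -> pd.Series:
        out: dict[str, float] = {}
        for c in self.duration_ms:
            out[f"dur_{c}"] = self.duration_ms[c]
        for c in self.occurrence_hz:
            out[f"occ_{c}"] = self.occurrence_hz[c]
        for c in self.coverage_pct:
            out[f"cov_{c}"] = self.coverage_pct[c]
        out.update(self.transition_pct)
        return pd.Series(out, name=self.subject_id)


def metrics_table(records: list[MetricsRecord]) -> pd.DataFrame:
    """One row per subject; columns dur_A..dur_D, occ_*, cov_*, tr_AB..tr_DC."""
    df = pd.DataFrame([r.to_series() for r in records])
    df.index.name = "subject"
    return df


# ---------------------------------------------------------------------------
# GFP and peaks


def compute_gfp(rec: Recording | np.ndarray, sfreq: float | None = None) -> GFPSeries:
    """Global field power: the spatial standard deviation of the topography.

    GFP(t) = sqrt( mean_c (v_c(t) - vbar(t))^2 ) with vbar the instantaneous
    channel mean (population SD across channels).
    """
    if isinstance(rec, Recording):
        data, sfreq = rec.data, rec.sfreq
    else:
        data = np.asarray(rec, dtype=float)
        if sfreq is None:
            raise ValueError("sfreq required when passing a bare array")
    if data.shape[0] < 2:
        raise ValueError("GFP requires at least two channels")
    values = data.std(axis=0, ddof=0)
    return GFPSeries(values=values, sfreq=float(sfreq))


def find_gfp_peaks(
    gfp: GFPSeries,
    mask: np.ndarray | None = None,
    exclusion: str = "mean+2sd",
) -> GFPSeries:
    """Detect strict local maxima of the GFP and flag outlier peaks.

    High-amplitude peaks are excluded as likely artifacts; with the default
    rule a peak is dropped when its GFP exceeds mean + 2*SD of all peak GFP
    values (sample SD). ``exclusion="2sd"`` uses the bare 2*SD threshold
    instead. Peaks inside masked samples are discarded.
    """
    v = gfp.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 samples to find peaks")
    peaks, _ = signal.find_peaks(v)  # strict local maxima
    if mask is not None:
        peaks = peaks[mask[peaks]]
    if peaks.size == 0:
        warnings.warn("no GFP peaks found", stacklevel=2)
        return GFPSeries(v, gfp.sfreq, peaks=peaks, excluded=peaks)
    pv = v[peaks]
    sd = pv.std(ddof=1) if pv.size > 1 else 0.0
    if exclusion == "mean+2sd":
        thresh = pv.mean() + 2.0 * sd
    elif exclusion == "2sd":
        thresh = 2.0 * sd
    else:
        raise ValueError(f"unknown exclusion rule {exclusion!r}")
    excluded = peaks[pv > thresh]
    return GFPSeries(v, gfp.sfreq, peaks=peaks, excluded=excluded)


# ---------------------------------------------------------------------------
# similarity


def spatial_similarity(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Pearson correlation across channels and its polarity-invariant
    absolute value.

    Raises on zero spatial variance (correlation undefined).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal channel counts")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-variance map: spatial correlation undefined")
    r = float(uc @ vc / (nu * nv))
    r = min(1.0, max(-1.0, r))
    return r, abs(r)


def _center_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center each map across channels and scale to unit L2 norm.

    Returns (unit maps, original norms). Zero-variance maps are rejected.
    """
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance map encountered")
    return centered / norms[:, None], norms


# ---------------------------------------------------------------------------
# GEV / CV


def gev(
    maps: np.ndarray,
    gfp: np.ndarray,
    templates: np.ndarray,
    assignments: np.ndarray,
) -> float:
    """Global explained variance of an assignment.

    GEV = sum_t (GFP_t * corr(v_t, a_{L(t)}))^2 / sum_t GFP_t^2 where corr
    is the spatial Pearson correlation.
    """
    gfp = np.asarray(gfp, dtype=float)
    denom = float(np.sum(gfp**2))
    if denom == 0.0:
        raise ValueError("all-zero GFP: GEV undefined")
    unit, _ = _center_normalize(np.asarray(maps, dtype=float))
    tunit, _ = _center_normalize(np.asarray(templates, dtype=float))
    corr = np.einsum("tc,tc->t", unit, tunit[assignments])
    return float(np.sum((gfp * corr) ** 2) / denom)


def cv_criterion(
    maps: np.ndarray,
    templates: np.ndarray,
    assignments: np.ndarray,
    n_channels: int | None = None,
    k: int | None = None,
) -> float:
    """Cross-validation criterion: residual topographic variance with a
    penalty on template count relative to channel count.

    sigma2 = sum_t (v_t'v_t - (a_{L(t)}'v_t)^2) / (T (C-1));
    CV = sigma2 * ((C-1)/(C-K-1))^2, with a the unit-norm templates.
    """
    maps = np.asarray(maps, dtype=float)
    templates = np.asarray(templates, dtype=float)
    C = n_channels if n_channels is not None else maps.shape[1]
    K = k if k is not None else templates.shape[0]
    if C <= K + 1:
        raise ValueError("CV criterion requires more channels than K+1")
    tunit, _ = _center_normalize(templates)
    proj = np.einsum("tc,tc->t", maps, tunit[assignments])
    resid = np.einsum("tc,tc->t", maps, maps) - proj**2
    sigma2 = float(resid.sum()) / (maps.shape[0] * (C - 1))
    return sigma2 * ((C - 1) / (C - K - 1)) ** 2


# ---------------------------------------------------------------------------
# modified k-means


def modified_kmeans(
    maps: np.ndarray,
    k: int = 4,
    n_init: int = 100,
    weights: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    rng: np.random.Generator | int | None = 0,
    center_update: str = "mean",
    provenance: str = "",
) -> TemplateSet:
    """Polarity-invariant modified k-means over topographic maps.

    Each restart seeds the k centers with maps sampled without replacement,
    assigns every map to the center of maximal absolute spatial
    correlation, and updates each center as the sign-aligned arithmetic
    mean of its members (a member is flipped when its correlation with the
    current center is negative), re-centered and re-normalized. Iteration
    stops when assignments stabilize or the GEV gain drops below ``tol``;
    the restart with the highest GEV wins. Empty clusters are re-seeded
    from the currently worst-fitted map.

    ``weights`` are the GFP values of the maps (used in the GEV objective);
    by default the maps' own spatial SDs are used. ``center_update`` may be
    "mean" (sign-aligned arithmetic mean, the default) or "eigen" (first
    principal eigenvector of the members' scatter, which maximizes the
    polarity-invariant fit exactly).
    """
    if center_update not in ("mean", "eigen"):
        raise ValueError(f"unknown center update {center_update!r}")
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    rng = np.random.default_rng(rng)

    unit, norms = _center_normalize(maps)
    C = maps.shape[1]
    if weights is None:
        weights = norms / np.sqrt(C)  # spatial SD of each map
    w2 = np.asarray(weights, dtype=float) ** 2
    denom = float(w2.sum())

    best_gev = -np.inf
    best_assign: np.ndarray | None = None
    best_centers: np.ndarray | None = None

    for _ in range(n_init):
        centers = unit[rng.choice(n, size=k, replace=False)].copy()
        assign = np.full(n, -1, dtype=int)
        prev_gev = -np.inf
        for _it in range(max_iter):
            corr = unit @ centers.T  # (n, k)
            new_assign = np.argmax(np.abs(corr), axis=1)
            fit = np.abs(corr[np.arange(n), new_assign])
            # re-seed empty clusters from the worst-fitted map
            for kk in range(k):
                if not np.any(new_assign == kk):
                    worst = int(np.argmin(fit))
                    centers[kk] = unit[worst]
                    new_assign[worst] = kk
                    fit[worst] = 1.0
            cur_gev = float(np.sum(w2 * fit**2) / denom)
            if np.array_equal(new_assign, assign) or cur_gev - prev_gev < tol:
                assign = new_assign
                break
            assign = new_assign
            prev_gev = cur_gev
            for kk in range(k):
                members = assign == kk
                if center_update == "eigen":
                    scatter = unit[members].T @ unit[members]
                    m = np.linalg.eigh(scatter)[1][:, -1]
                else:  # sign-aligned arithmetic mean
                    signs = np.sign(corr[members, kk])
                    signs[signs == 0] = 1.0
                    m = (signs[:, None] * unit[members]).mean(axis=0)
                m = m - m.mean()
                nm = np.linalg.norm(m)
                if nm > 0:
                    centers[kk] = m / nm
        corr = unit @ centers.T
        fit = np.abs(corr[np.arange(n), assign])
        g = float(np.sum(w2 * fit**2) / denom)
        if g > best_gev:
            best_gev = g
            best_assign = assign.copy()
            best_centers = centers.copy()

    cv = cv_criterion(maps - maps.mean(axis=1, keepdims=True),
                      best_centers, best_assign, n_channels=C, k=k)
    return TemplateSet(
        maps=best_centers,
        gev=best_gev,
        cv=cv,
        provenance=provenance,
        restarts=n_init,
    )


# ---------------------------------------------------------------------------
# two-level clustering


def _scalp_data(rec: Recording) -> np.ndarray:
    """Common-average-referenced scalp data (spatial mean removed per
    sample), the form in which all topographic comparisons operate."""
    return rec.data - rec.data.mean(axis=0, keepdims=True)


def cluster_individual(
    rec: Recording,
    k: int = 4,
    n_init: int = 100,
    exclusion: str = "mean+2sd",
    rng: np.random.Generator | int | None = 0,
    max_iter: int = 1000,
    center_update: str = "mean",
) -> TemplateSet:
    """First-level clustering of one subject's GFP-peak topographies."""
    data = _scalp_data(rec)
    gfp_series = compute_gfp(data, rec.sfreq)
    gfp_series = find_gfp_peaks(gfp_series, mask=rec.good_mask(), exclusion=exclusion)
    idx = gfp_series.accepted_peaks()
    if idx.size < k:
        raise ValueError(f"fewer than k={k} usable GFP peaks")
    peak_maps = data[:, idx].T
    return modified_kmeans(
        peak_maps, k=k, n_init=n_init,
        weights=gfp_series.values[idx], rng=rng,
        max_iter=max_iter, center_update=center_update,
        provenance=rec.subject_id or "individual",
    )


def match_canonical(
    templates: TemplateSet, canonical: TemplateSet
) -> tuple[TemplateSet, float]:
    """Label templates A-D by the one-to-one matching to canonical maps
    that maximizes total polarity-invariant similarity.

    Returns the reordered, labeled set and the mean matched similarity.
    A warning is emitted when the mean similarity falls below 0.5
    (non-canonical solution).
    """
    tu, _ = _center_normalize(templates.maps)
    cu, _ = _center_normalize(canonical.maps)
    sim = np.abs(tu @ cu.T)  # (k, k_canon)
    rows, cols = linear_sum_assignment(-sim)
    order = rows[np.argsort(cols)]
    labels = tuple(canonical.labels[c] for c in np.sort(cols))
    mean_sim = float(sim[rows, cols].mean())
    if mean_sim < 0.5:
        warnings.warn(
            f"canonical label assignment has low mean similarity {mean_sim:.2f}",
            stacklevel=2,
        )
    return templates.reorder(order, labels), mean_sim


def cluster_group(
    individual_sets: list[TemplateSet],
    canonical: TemplateSet,
    k: int = 4,
    n_init: int = 100,
    rng: np.random.Generator | int | None = 0,
    max_iter: int = 1000,
    center_update: str = "mean",
) -> TemplateSet:
    """Second-level clustering: pool all individual templates, cluster, and
    assign canonical labels A-D."""
    if len(individual_sets) < 2:
        raise ValueError("group clustering requires at least two subjects")
    pooled = np.vstack([ts.maps for ts in individual_sets])
    group = modified_kmeans(pooled, k=k, n_init=n_init, rng=rng,
                            max_iter=max_iter, center_update=center_update,
                            provenance="group")
    labeled, _ = match_canonical(group, canonical)
    return labeled


# ---------------------------------------------------------------------------
# backfitting and metrics


def backfit(
    rec: Recording,
    templates: TemplateSet,
    min_duration_ms: float = 0.0,
) -> LabelSequence:
    """Assign every unmasked sample to the template of maximal absolute
    spatial correlation.

    Ties go to the lowest class index (A before B before C before D).
    Zero-variance samples inherit the previous valid label, or the next
    one at the start of the sequence. No temporal smoothing is applied by
    default; ``min_duration_ms > 0`` relabels runs shorter than the
    threshold with the preceding run's label (within unmasked spans).
    """
    if templates.labels is None:
        raise ValueError("backfit requires a labeled template set")
    mask = rec.good_mask()
    if not mask.any():
        raise ValueError("no unmasked samples to backfit")
    data = _scalp_data(rec)
    norms = np.linalg.norm(data, axis=0)
    tunit, _ = _center_normalize(templates.maps)
    corr = np.zeros((templates.k, rec.n_samples))
    valid = norms > 0
    corr[:, valid] = (tunit @ data[:, valid]) / norms[valid]
    absc = np.abs(corr)
    labels = absc.argmax(axis=0)  # argmax tie -> lowest class index
    fitcorr = absc[labels, np.arange(rec.n_samples)]

    # zero-variance samples inherit the nearest previous valid label
    if not valid.all():
        fitcorr = fitcorr.astype(float)
        fitcorr[~valid] = np.nan
        lab = labels.astype(float)
        lab[~valid] = np.nan
        s = pd.Series(lab).ffill().bfill()
        labels = s.to_numpy().astype(np.int64)

    labels = labels.astype(np.int64)
    labels[~mask] = -1
    if min_duration_ms > 0:
        labels = _reject_short_runs(
            labels, int(round(min_duration_ms * rec.sfreq / 1000.0))
        )
    fitcorr = np.asarray(fitcorr, dtype=float)
    fitcorr[~mask] = np.nan
    return LabelSequence(
        labels=labels,
        sfreq=rec.sfreq,
        correlation=fitcorr,
        class_names=tuple(templates.labels),
        subject_id=rec.subject_id,
    )


def _reject_short_runs(labels: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge runs shorter than ``min_samples`` into the preceding run
    (or the following one at a span start); masked samples untouched."""
    out = labels.copy()
    mask = out >= 0
    span_edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = np.r_[0, span_edges + 1, out.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not mask[a]:
            continue
        seg = out[a:b]
        rl, rn = _runs_in_span(seg)
        keep = rn >= min_samples
        if not keep.any():
            continue
        # assign each short run the label of the nearest preceding kept run
        kept_labels = []
        prev = rl[keep][0]
        for lab, ok in zip(rl, keep):
            if ok:
                prev = lab
            kept_labels.append(prev)
        out[a:b] = np.repeat(kept_labels, rn)
    return out


def _runs_in_span(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode one unmasked span: (run labels, run lengths)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, labels.size]
    return labels[starts], ends - starts


def compute_metrics(
    seq: LabelSequence,
    k: int | None = None,
    include_boundary_runs: bool = True,
) -> MetricsRecord:
    """Temporal statistics of one label sequence.

    Runs are maximal constant-label stretches within unmasked spans; no
    run or transition is counted across a mask boundary. Transition
    percentages are joint over all observed label changes (they sum to
    100 when any transition exists). Runs touching a span edge are
    truncated by the recording (or mask) rather than by a genuine state
    change; they are included by default (the bias is negligible at
    minutes-long recordings) and dropped from duration/occurrence with
    ``include_boundary_runs=False``.
    """
    labels = np.asarray(seq.labels)
    names = seq.class_names
    k = k if k is not None else len(names)
    mask = labels >= 0
    n_good = int(mask.sum())
    if n_good == 0:
        raise ValueError("no unmasked samples")
    seconds = n_good / seq.sfreq

    run_labels: list[np.ndarray] = []
    run_lengths: list[np.ndarray] = []
    trans_counts = np.zeros((k, k), dtype=np.int64)
    # split into contiguous unmasked spans
    span_edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = np.r_[0, span_edges + 1, labels.size]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not mask[a]:
            continue
        rl, rn = _runs_in_span(labels[a:b])
        if rl.size > 1:
            np.add.at(trans_counts, (rl[:-1], rl[1:]), 1)
        if not include_boundary_runs:
            rl, rn = rl[1:-1], rn[1:-1]
        run_labels.append(rl)
        run_lengths.append(rn)
    rl = np.concatenate(run_labels)
    rn = np.concatenate(run_lengths)
    if rl.size == 0:  # every run touched a boundary
        rl = np.concatenate([_runs_in_span(labels[a:b])[0]
                             for a, b in zip(bounds[:-1], bounds[1:]) if mask[a]])
        rn = np.concatenate([_runs_in_span(labels[a:b])[1]
                             for a, b in zip(bounds[:-1], bounds[1:]) if mask[a]])

    duration = {}
    occurrence = {}
    coverage = {}
    counts = np.bincount(labels[mask], minlength=k)
    for c in range(k):
        sel = rl == c
        duration[names[c]] = (
            float(rn[sel].mean()) * 1000.0 / seq.sfreq if sel.any() else float("nan")
        )
        occurrence[names[c]] = float(sel.sum()) / seconds
        coverage[names[c]] = 100.0 * counts[c] / n_good

    total_trans = int(trans_counts.sum())
    warning = None
    transition = {}
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            key = f"tr_{names[i]}{names[j]}"
            transition[key] = (
                100.0 * trans_counts[i, j] / total_trans if total_trans else 0.0
            )
    if total_trans == 0:
        warning = "no transitions observed"
    return MetricsRecord(
        subject_id=seq.subject_id,
        duration_ms=duration,
        occurrence_hz=occurrence,
        coverage_pct=coverage,
        transition_pct=transition,
        n_transitions=total_trans,
        warning=warning,
    )
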