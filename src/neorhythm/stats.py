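"""Group statistics: rising-slope metrics, cluster-based permutation tests,
ROI aggregation, and repeated-measures ANOVA.

The slope of the HbO rise is

    slope = (HbO_peak - HbO_onset) / (t_peak - t_onset)

with the peak searched over the post-onset window, and the normalized slope
contrasting conditions as (slope_RC - slope_AC) / (slope_RC + slope_AC).

Cluster-based permutation tests control the family-wise error of pointwise
paired t-tests: supra-threshold points (p < alpha at the cluster-forming
stage) are grouped into contiguous temporal runs or spatially connected
channel sets of equal sign, each cluster scored by its summed t, and the
observed cluster masses compared against the permutation distribution of the
maximal mass under participant-level sign flips of the paired differences
(exact under exchangeability; exhaustive enumeration is used automatically
for small cohorts).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spst

from .config import ClusterConfig
from .montage import ANALYSIS_ROIS, Montage

CONDITIONS = ("rhythmic", "arrhythmic")
HEMISPHERES = ("left", "right")
ROI_WINDOW_S = (8.0, 12.0)


# --------------------------------------------------------------------------
# rising slope (Eq. 1 / Eq. 2 style metrics)
# --------------------------------------------------------------------------

@dataclass
class SlopeResult:
    """Per participant x channel x condition rising-slope metrics."""

    slope: np.ndarray            # (n_part, n_ch, 2)
    peak_value: np.ndarray
    peak_time_s: np.ndarray
    onset_value: np.ndarray
    normalized: np.ndarray       # (n_part, n_ch)


def rising_slope(
    stack: np.ndarray,
    times_s: np.ndarray,
    post_window_s: tuple[float, float] = (0.0, 25.0),
) -> SlopeResult:
    """Rising slope of condition-averaged responses.

    ``stack`` is (n_participants, n_channels, 2 conditions, n_times) at the
    analysis rate; the onset value is taken at t = 0 and the peak is the
    maximum strictly after onset (so the slope denominator is positive).
    Normalized slopes with a zero denominator are returned as NaN with a
    warning.
    """
    i_onset = int(np.argmin(np.abs(times_s - 0.0)))
    post = (times_s > post_window_s[0]) & (times_s <= post_window_s[1])
    idx_post = np.flatnonzero(post)
    seg = stack[..., idx_post]
    k = np.nanargmax(np.where(np.isnan(seg), -np.inf, seg), axis=-1)
    k = np.where(np.isnan(seg).all(axis=-1), 0, k)
    peak_val = np.take_along_axis(seg, k[..., None], axis=-1)[..., 0]
    peak_t = times_s[idx_post][k]
    onset_val = stack[..., i_onset]
    slope = (peak_val - onset_val) / (peak_t - times_s[i_onset])
    s_rc = slope[..., CONDITIONS.index("rhythmic")]
    s_ac = slope[..., CONDITIONS.index("arrhythmic")]
    denom = s_rc + s_ac
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = (s_rc - s_ac) / denom
    zero = np.isclose(denom, 0.0) & ~np.isnan(denom)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} normalized slopes undefined (zero denominator)")
        normalized = np.where(zero, np.nan, normalized)
    return SlopeResult(
        slope=slope,
        peak_value=peak_val,
        peak_time_s=peak_t,
        onset_value=onset_val,
        normalized=normalized,
    )


# --------------------------------------------------------------------------
# cluster-based permutation machinery
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    members: np.ndarray  # indices (time points or channels)
    t_sum: float
    p_perm: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold: np.ndarray  # per-point cluster-forming |t| threshold
    null_max_mass: np.ndarray
    n_permutations: int
    exhaustive: bool

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_perm < alpha]


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """t statistics of one-sample tests on columns of (n_subj, n_points).

    NaN entries (participants without data at a point/channel) are ignored;
    columns with fewer than two observations get t = 0.
    """
    valid = ~np.isnan(diff)
    n = valid.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(diff, axis=0)
        sd = np.nanstd(diff, axis=0, ddof=1)
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return np.where(n < 2, 0.0, t)


def _t_thresholds(diff: np.ndarray, alpha: float) -> np.ndarray:
    """Per-column cluster-forming |t| thresholds (df varies with NaN count)."""
    n = (~np.isnan(diff)).sum(axis=0)
    thr = np.full(diff.shape[1], np.inf)
    ok = n >= 2
    thr[ok] = spst.t.ppf(1 - alpha / 2, n[ok] - 1)
    return thr


def _temporal_clusters(t: np.ndarray, thr: np.ndarray) -> list[np.ndarray]:
    """Runs of contiguous supra-threshold points of equal sign."""
    out = []
    sig = np.abs(t) > thr
    k = 0
    while k < t.size:
        if not sig[k]:
            k += 1
            continue
        j = k
        while j + 1 < t.size and sig[j + 1] and np.sign(t[j + 1]) == np.sign(t[k]):
            j += 1
        out.append(np.arange(k, j + 1))
        k = j + 1
    return out


def _spatial_clusters(t: np.ndarray, thr: np.ndarray, adjacency: np.ndarray, min_size: int) -> list[np.ndarray]:
    """Connected same-sign supra-threshold channel sets (singletons allowed)."""
    sig = np.abs(t) > thr
    seen = np.zeros(t.size, dtype=bool)
    out = []
    for start in np.flatnonzero(sig):
        if seen[start]:
            continue
        sign = np.sign(t[start])
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adjacency[u]):
                if sig[v] and not seen[v] and np.sign(t[v]) == sign:
                    seen[v] = True
                    stack.append(v)
        if len(comp) >= min_size:
            out.append(np.array(sorted(comp)))
    return out


def _max_mass(t: np.ndarray, thr: np.ndarray, clusterer) -> float:
    clusters = clusterer(t, thr)
    if not clusters:
        return 0.0
    return max(abs(t[c].sum()) for c in clusters)


def _sign_flip_null(
    diff: np.ndarray,
    thr: np.ndarray,
    clusterer,
    config: ClusterConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    n = diff.shape[0]
    exhaustive = n <= config.exhaustive_max_n and 2**n <= config.n_permutations
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice([1.0, -1.0], size=(config.n_permutations, n))
    null = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        null[i] = _max_mass(_paired_t(diff * s[:, None]), thr, clusterer)
    return null, exhaustive


def _perm_p(obs: float, null: np.ndarray, exhaustive: bool) -> float:
    if exhaustive:
        return float((null >= obs - 1e-12).mean())
    return float((1 + (null >= obs - 1e-12).sum()) / (1 + null.size))


def _cluster_test(
    diff: np.ndarray,
    clusterer,
    config: ClusterConfig,
    rng: np.random.Generator,
) -> ClusterResult:
    n = diff.shape[0]
    if n < 2:
        raise ValueError("cluster test requires at least 2 participants")
    thr = _t_thresholds(diff, config.alpha_cluster_forming)
    t_obs = _paired_t(diff)
    clusters_idx = clusterer(t_obs, thr)
    null, exhaustive = _sign_flip_null(diff, thr, clusterer, config, rng)
    clusters = [
        Cluster(
            members=c,
            t_sum=float(t_obs[c].sum()),
            p_perm=_perm_p(abs(t_obs[c].sum()), null, exhaustive),
        )
        for c in clusters_idx
    ]
    clusters.sort(key=lambda c: c.p_perm)
    return ClusterResult(
        clusters=clusters,
        t_map=t_obs,
        threshold=thr,
        null_max_mass=null,
        n_permutations=null.size,
        exhaustive=exhaustive,
    )


def temporal_cluster_test(
    series_a: np.ndarray,
    series_b: np.ndarray | float = 0.0,
    config: ClusterConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Temporal cluster permutation test on participant-aligned time series.

    ``series_a`` is (n_participants, n_times); ``series_b`` is a matched
    array (paired contrast) or a scalar baseline.  The null distribution is
    built from sign flips of the participant-wise differences; enumeration is
    exhaustive when 2**n does not exceed the permutation budget.
    """
    config = config or ClusterConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diff = series_a - series_b
    return _cluster_test(diff, _temporal_clusters, config, rng)


def spatial_cluster_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    montage: Montage,
    config: ClusterConfig | None = None,
    seed: int | np.random.Generator = 0,
    channel_indices: np.ndarray | None = None,
) -> ClusterResult:
    """Spatial cluster permutation test on per-channel paired values.

    ``values_a``/``values_b`` are (n_participants, n_channels) (e.g. rising
    slopes per condition).  Channels are neighbors when their midpoints lie
    within the configured radius on the same hemisphere; by default the
    radius is the smallest giving every channel at least two neighbors.
    ``channel_indices`` maps columns to montage channel indices when a
    retained subset is analyzed.
    """
    config = config or ClusterConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radius = config.neighbor_radius_mm or montage.default_neighbor_radius(
        min_neighbors=max(2, config.min_neighbors)
    )
    adj = montage.adjacency(radius)
    if channel_indices is not None:
        adj = adj[np.ix_(channel_indices, channel_indices)]
    diff = values_a - values_b

    def clusterer(t, thr):
        return _spatial_clusters(t, thr, adj, config.min_cluster_size)

    return _cluster_test(diff, clusterer, config, rng)


# --------------------------------------------------------------------------
# ROI aggregation
# --------------------------------------------------------------------------

def roi_aggregate(
    stack: np.ndarray,
    times_s: np.ndarray,
    montage: Montage,
    retained: np.ndarray | None = None,
    window_s: tuple[float, float] = ROI_WINDOW_S,
) -> pd.DataFrame:
    """Participant x condition x ROI x hemisphere mean HbO over 8-12 s.

    The response is first averaged over the window (inclusive) per channel,
    then over retained channels of each ROI.  Returns a long-format table
    with columns participant, condition, roi, hemisphere, hbo.
    """
    n_part = stack.shape[0]
    if retained is None:
        retained = np.ones(stack.shape[1], dtype=bool)
    sel_t = (times_s >= window_s[0]) & (times_s <= window_s[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        win = np.nanmean(stack[..., sel_t], axis=-1)  # (n_part, n_ch, 2)
    rows = []
    for roi in ANALYSIS_ROIS:
        for hemi in HEMISPHERES:
            idx = [
                c.index
                for c in montage.channels_of(hemisphere=hemi, region=roi)
                if retained[c.index]
            ]
            if not idx:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = np.nanmean(win[:, idx, :], axis=1)  # (n_part, 2)
            for p in range(n_part):
                for ci, cond in enumerate(CONDITIONS):
                    rows.append(
                        dict(
                            participant=p,
                            condition=cond,
                            roi=roi,
                            hemisphere=hemi,
                            hbo=m[p, ci],
                        )
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------

@dataclass
class EffectResult:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float
    ss_effect: float = 0.0
    ss_error: float = 0.0
    gg_epsilon: float = 1.0
    p_gg: float | None = None
    mauchly_p: float | None = None


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    table: pd.DataFrame

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


def _cell_matrix(df: pd.DataFrame, factors: list[str], value: str = "hbo"):
    """Pivot to (n_subjects, n_cells) with cells ordered by factor levels."""
    levels = [list(dict.fromkeys(df[f])) for f in factors]
    piv = df.pivot_table(index="participant", columns=factors, values=value, sort=False)
    cols = list(itertools.product(*levels)) if len(factors) > 1 else levels[0]
    piv = piv[cols]
    if piv.isna().any().any():
        missing = piv.columns[piv.isna().any()].tolist()
        raise ValueError(f"missing cells in the repeated-measures design: {missing}")
    return piv.to_numpy(), levels


def _contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal polynomial-free contrast (Helmert-like)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_mauchly(effect_scores: np.ndarray) -> tuple[float, float | None]:
    """Greenhouse-Geisser epsilon and Mauchly p from subject x contrast
    scores of one within-subject effect (d columns)."""
    d = effect_scores.shape[1]
    if d <= 1:
        return 1.0, None
    n = effect_scores.shape[0]
    cov = np.cov(effect_scores, rowvar=False, ddof=1)
    tr = np.trace(cov)
    eps = tr**2 / (d * (cov**2).sum())
    eps = float(min(1.0, max(1.0 / d, eps)))
    # Mauchly's W with chi-square approximation
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 1e-300, None)
    W = np.prod(eig) / (eig.mean() ** d)
    f = 1 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(max(W, 1e-300))
    df = d * (d + 1) // 2 - 1
    p = float(spst.chi2.sf(chi2, df)) if df > 0 else None
    return eps, p


def rm_anova(table: pd.DataFrame, factors: list[str] | None = None) -> AnovaResult:
    """Fully within-subject ANOVA on a balanced long-format table.

    ``table`` needs columns participant, hbo and the factor columns
    (default: condition, roi, hemisphere — the three-way design).  For each
    effect the error term is its interaction with subjects; partial eta
    squared is SS_effect / (SS_effect + SS_error).  Greenhouse-Geisser
    corrected p-values are reported whenever Mauchly's test rejects
    sphericity (effects with more than one numerator df).
    """
    factors = factors or ["condition", "roi", "hemisphere"]
    data, levels = _cell_matrix(table, factors)
    n = data.shape[0]
    if n < 2:
        raise ValueError("rm_anova needs at least two participants")
    shape = [len(lv) for lv in levels]
    cube = data.reshape([n] + shape)  # subject x factor1 x factor2 ...
    effects: dict[str, EffectResult] = {}
    rows = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(range(len(factors)), r):
            name = " x ".join(factors[i] for i in combo)
            # contrast matrices: effect contrasts on involved factors,
            # averaging vectors elsewhere
            mats = []
            for i, k in enumerate(shape):
                if i in combo:
                    mats.append(_contrast(k))
                else:
                    mats.append(np.full((1, k), 1 / k))
            scores = cube
            for ax, m in enumerate(mats):
                scores = np.tensordot(scores, m, axes=([1 + ax], [1]))
                scores = np.moveaxis(scores, -1, 1 + ax)
            scores = scores.reshape(n, -1)  # (n, d) effect scores per subject
            d = scores.shape[1]
            # contrast-space SS differ from cell-space SS by the number of
            # levels averaged out; rescale so the partition sums to SS_total
            m_scale = float(np.prod([shape[i] for i in range(len(shape)) if i not in combo]))
            mean = scores.mean(axis=0)
            ss_effect = m_scale * n * float(mean @ mean)
            resid = scores - mean
            ss_error = m_scale * float((resid**2).sum())
            df_num = d
            df_den = d * (n - 1)
            ms_e = ss_error / df_den
            # machine-zero effect and error SS make the F ratio meaningless
            tol = 1e-12 * max(1.0, float((data**2).sum()))
            if ss_effect < tol and ss_error < tol:
                F = 0.0
            elif ms_e > 0:
                F = (ss_effect / df_num) / ms_e
            else:
                F = np.inf
            p = float(spst.f.sf(F, df_num, df_den))
            eta = ss_effect / (ss_effect + ss_error) if ss_effect + ss_error > 0 else 0.0
            eps, mauchly_p = _gg_mauchly(scores)
            p_gg = float(spst.f.sf(F, df_num * eps, df_den * eps)) if d > 1 else None
            eff = EffectResult(
                name=name,
                F=float(F),
                df_num=df_num,
                df_den=df_den,
                p=p,
                eta_p2=float(eta),
                ss_effect=ss_effect,
                ss_error=ss_error,
                gg_epsilon=eps,
                p_gg=p_gg,
                mauchly_p=mauchly_p,
            )
            effects[name] = eff
            rows.append(
                dict(
                    effect=name, F=eff.F, df_num=df_num, df_den=df_den, p=p,
                    eta_p2=eff.eta_p2, ss_effect=ss_effect, ss_error=ss_error,
                    gg_epsilon=eps,
                    p_gg=np.nan if p_gg is None else p_gg,
                    mauchly_p=np.nan if mauchly_p is None else mauchly_p,
                )
            )
    return AnovaResult(effects=effects, table=pd.DataFrame(rows))


def tukey_kramer(table: pd.DataFrame, factor: str = "roi") -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons on a within-subject factor.

    Cell means are compared with the studentized range using the
    factor-by-subject interaction mean square as the error term.
    """
    data, levels = _cell_matrix(table.groupby(["participant", factor], sort=False, as_index=False)["hbo"].mean(), [factor])
    n, k = data.shape
    means = data.mean(axis=0)
    resid = data - data.mean(axis=1, keepdims=True) - means + data.mean()
    df_err = (n - 1) * (k - 1)
    ms_err = float((resid**2).sum()) / df_err
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
        p = float(spst.studentized_range.sf(q, k, df_err))
        rows.append(dict(a=levels[0][i], b=levels[0][j], mean_a=means[i],
                         mean_b=means[j], q=q, p_tukey=p))
    return pd.DataFrame(rows)


def drop_incomplete_participants(table: pd.DataFrame) -> pd.DataFrame:
    """Remove participants with any missing (NaN) ROI-table cell.

    Participants who lose every retained channel of a region (e.g. through
    trial rejection) cannot enter the fully balanced repeated-measures
    design, mirroring the study practice of discarding participants with too
    few remaining trials.
    """
    bad = table[table.hbo.isna()].participant.unique()
    if bad.size:
        warnings.warn(f"dropping {bad.size} participant(s) with incomplete ROI cells")
    return table[~table.participant.isin(bad)].copy()


@dataclass
class AnovaSuite:
    """The full ANOVA battery: one three-way plus the five follow-ups."""

    three_way: AnovaResult
    by_condition: dict[str, AnovaResult]   # ROI x hemisphere per condition
    by_roi: dict[str, AnovaResult]         # condition x hemisphere per ROI
    posthoc_roi: pd.DataFrame


def anova_suite(table: pd.DataFrame) -> AnovaSuite:
    """Run the three-way rANOVA and all follow-up analyses."""
    three = rm_anova(table, ["condition", "roi", "hemisphere"])
    by_cond = {
        cond: rm_anova(table[table.condition == cond], ["roi", "hemisphere"])
        for cond in CONDITIONS
    }
    by_roi = {
        roi: rm_anova(table[table.roi == roi], ["condition", "hemisphere"])
        for roi in ANALYSIS_ROIS
    }
    return AnovaSuite(
        three_way=three,
        by_condition=by_cond,
        by_roi=by_roi,
        posthoc_roi=tukey_kramer(table, "roi"),
    )
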