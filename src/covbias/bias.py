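"""Coverage-bias dissection: GC effects, predictor importance, and
variant-site-density depletion.

The predictor-importance analysis asks which of four interval features —
GC content, interval length, multimapping fraction (MF), and inclusion in
the capture design — drives normalized coverage. Three model families are
fitted: ordinary least squares on the continuous normalized mean
(importance = |t| of each coefficient), L2-free logistic regression on the
low-coverage label (importance = |z| of standardized coefficients), and a
random-forest classifier (importance = mean impurity decrease, mtry = 2
features per split). Importances are rescaled within each family so the
top predictor scores 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from .coverage import CoverageTrack
from .intervals import IntervalSet, gc_fraction

__all__ = [
    "VariantSite",
    "ImportanceResult",
    "VSDResamplingResult",
    "gc_context",
    "assign_gc_deciles",
    "gc_decile_coverage",
    "extreme_gc_comparison",
    "fit_importance",
    "variant_site_density",
    "vsd_resampling_test",
]

PREDICTORS = ["gc", "length", "mf", "targeted"]


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 0-based
    gc_context: float = float("nan")
    decile: int = 0


@dataclass
class ImportanceResult:
    """Per-predictor importance, scaled to max 100 within each family."""

    linear_regression: pd.Series
    linear_classification: pd.Series | None
    random_forest: pd.Series | None
    cv_metrics: pd.DataFrame | None
    notes: list[str]


@dataclass
class VSDResamplingResult:
    observed_mean_vsd: float
    null_means: np.ndarray
    n_resamples: int
    set_size: int
    empirical_p: float
    alternative: str


# ---------------------------------------------------------------------------
# GC deciles at variant sites
# ---------------------------------------------------------------------------

def gc_context(
    sites: list[VariantSite], genome, flank: int = 50
) -> list[VariantSite]:
    """Annotate each site with the GC fraction of its +-``flank`` bp window
    ``[pos - flank, pos + flank + 1)`` (window truncated at contig edges).

    ``genome`` is a FASTA path, an open :class:`pyfaidx.Fasta`, or a plain
    ``{chrom: sequence}`` mapping.
    """
    fasta = Fasta(genome) if isinstance(genome, str) else genome
    for site in sites:
        if site.chrom not in fasta:
            raise KeyError(f"chromosome {site.chrom!r} absent from genome FASTA")
        contig = fasta[site.chrom]
        lo = max(0, site.pos - flank)
        hi = min(len(contig), site.pos + flank + 1)
        site.gc_context = gc_fraction(str(contig[lo:hi]))
    return sites


def assign_gc_deciles(sites: list[VariantSite], n_groups: int = 10) -> list[VariantSite]:
    """Split sites into ``n_groups`` equal-count groups by GC context.

    Sites are ranked by GC with ties broken by genomic order (stable sort on
    the input order, which is expected sorted); group sizes differ by at
    most 1. Decile 1 = lowest GC.
    """
    usable = [s for s in sites if np.isfinite(s.gc_context)]
    if not usable:
        raise ValueError("no sites with defined GC context")
    order = sorted(range(len(usable)), key=lambda k: (usable[k].gc_context, k))
    bounds = np.linspace(0, len(usable), n_groups + 1).round().astype(int)
    for g in range(n_groups):
        for k in order[bounds[g] : bounds[g + 1]]:
            usable[k].decile = g + 1
    return sites


def gc_decile_coverage(
    sites: list[VariantSite],
    track: CoverageTrack,
    mean_depth: float | None = None,
    n_groups: int = 10,
) -> pd.DataFrame:
    """Normalized depth at variant sites, summarized per GC decile.

    Sites must already carry GC context (see :func:`gc_context`); deciles
    are (re)assigned here. Sites outside the track universe are excluded
    and counted in the ``n_excluded`` attribute of the result. Returns one
    row per decile with mean and median normalized site depth, the median
    GC of the decile, and the site count.
    """
    from .intervals import GenomicInterval

    if mean_depth is None:
        mean_depth = track.mean_depth()
    if mean_depth <= 0:
        raise ValueError("normalization denominator must be positive")
    assign_gc_deciles(sites, n_groups=n_groups)
    rows = []
    n_excluded = 0
    for site in sites:
        if not np.isfinite(site.gc_context):
            n_excluded += 1
            continue
        try:
            depth = track.depth_over(GenomicInterval(site.chrom, site.pos, site.pos + 1))[0]
        except KeyError:
            n_excluded += 1
            continue
        rows.append({"decile": site.decile, "gc": site.gc_context, "norm": depth / mean_depth})
    if not rows:
        raise ValueError("no usable variant sites inside the track universe")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("decile")
        .agg(
            mean_norm=("norm", "mean"),
            median_norm=("norm", "median"),
            median_gc=("gc", "median"),
            n_sites=("norm", "size"),
        )
        .reset_index()
    )
    out.attrs["n_excluded"] = n_excluded
    return out


# ---------------------------------------------------------------------------
# Extreme-GC comparison
# ---------------------------------------------------------------------------

def extreme_gc_comparison(
    summaries: pd.DataFrame,
    low_band: tuple[float, float] = (0.0, 0.2),
    high_band: tuple[float, float] = (0.8, 1.0),
) -> dict:
    """Compare normalized coverage of extreme-GC intervals to the rest.

    Bands select intervals by GC (half-open [lo, hi), except the high band
    is closed at 1). Each non-empty band is tested against the remaining
    intervals with a two-sided Wilcoxon rank-sum test. Totals are in bp.
    """
    gc = summaries["gc"].to_numpy(dtype=float)
    norm = summaries["norm_mean"].to_numpy(dtype=float)
    lengths = summaries["length"].to_numpy()
    out: dict = {}
    for label, (lo, hi) in (("low_gc", low_band), ("high_gc", high_band)):
        inband = (gc >= lo) & ((gc < hi) | (hi >= 1.0) & (gc <= hi))
        entry = {
            "n_intervals": int(inband.sum()),
            "total_bp": int(lengths[inband].sum()),
            "values": norm[inband],
            "median": float(np.median(norm[inband])) if inband.any() else float("nan"),
            "p_value": float("nan"),
        }
        if inband.any() and (~inband).any():
            entry["p_value"] = float(
                stats.mannwhitneyu(norm[inband], norm[~inband], alternative="two-sided").pvalue
            )
        out[label] = entry
    out["remainder_median"] = float(np.median(norm)) if len(norm) else float("nan")
    return out


# ---------------------------------------------------------------------------
# Predictor importance
# ---------------------------------------------------------------------------

def fit_importance(
    table: pd.DataFrame,
    low_cutoff: float = 0.1,
    cv_folds: int = 5,
    rf_mtry: int = 2,
    seed: int | None = None,
    response: str = "norm_mean",
) -> ImportanceResult:
    """Relative importance of gc/length/mf/targeted for interval coverage.

    ``table`` needs columns ``gc, length, mf, targeted`` and the response.
    The low-coverage label for the classifiers is ``response < low_cutoff``;
    classifier families are skipped (with a diagnostic note) when only one
    class is present. Deterministic under ``seed``.
    """
    import statsmodels.api as sm
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import accuracy_score, cohen_kappa_score
    from sklearn.model_selection import StratifiedKFold

    if len(table) < 50:
        raise ValueError("need >= 50 intervals for a stable importance fit")
    X = table[PREDICTORS].astype(float).to_numpy()
    y_cont = table[response].to_numpy(dtype=float)
    y_bin = (y_cont < low_cutoff).astype(int)
    notes: list[str] = []

    def _rescale(vals: np.ndarray) -> pd.Series:
        # a constant predictor (collinear with the intercept) gets nan/inf
        # statistics; it carries no information, score it 0
        vals = np.abs(np.asarray(vals, dtype=float))
        vals[~np.isfinite(vals)] = 0.0
        top = vals.max()
        scaled = 100.0 * vals / top if top > 0 else np.zeros_like(vals)
        return pd.Series(scaled, index=PREDICTORS)

    # (a) linear regression: |t| of each coefficient
    ols = sm.OLS(y_cont, sm.add_constant(X, has_constant="add")).fit()
    lin_imp = _rescale(ols.tvalues[1:])

    log_imp = None
    rf_imp = None
    cv_rows = []
    if y_bin.min() == y_bin.max():
        notes.append("single-class label vector; classifiers skipped")
    else:
        # (b) logistic regression on standardized predictors: |z|; a
        # (near-)separable label makes the unpenalized fit diverge, in which
        # case an L2-penalized fit's |standardized coefficient| stands in
        Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        import warnings as _warnings

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                logit = sm.Logit(y_bin, sm.add_constant(Xs)).fit(disp=0, maxiter=200)
            if not logit.mle_retvals.get("converged", False) or not np.all(
                np.isfinite(logit.bse)
            ):
                raise ValueError("unpenalized logistic fit did not converge")
            log_imp = _rescale(logit.tvalues[1:])
        except Exception:
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(C=1.0, max_iter=1000).fit(Xs, y_bin)
            log_imp = _rescale(clf.coef_[0])
            notes.append("logistic: separable label, penalized coefficients used")

        # (c) random forest: impurity decrease, mtry features per split
        rf = RandomForestClassifier(
            n_estimators=500, max_features=rf_mtry, random_state=seed
        )
        rf.fit(X, y_bin)
        rf_imp = _rescale(rf.feature_importances_)

        if cv_folds and cv_folds >= 2 and y_bin.sum() >= cv_folds and (1 - y_bin).sum() >= cv_folds:
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            for fold, (tr, te) in enumerate(skf.split(X, y_bin)):
                rf_cv = RandomForestClassifier(
                    n_estimators=200, max_features=rf_mtry, random_state=seed
                ).fit(X[tr], y_bin[tr])
                pred = rf_cv.predict(X[te])
                cv_rows.append(
                    {
                        "fold": fold,
                        "model": "random_forest",
                        "accuracy": accuracy_score(y_bin[te], pred),
                        "kappa": cohen_kappa_score(y_bin[te], pred),
                    }
                )
        else:
            notes.append("too few minority-class rows for cross-validation")

    return ImportanceResult(
        linear_regression=lin_imp,
        linear_classification=log_imp,
        random_forest=rf_imp,
        cv_metrics=pd.DataFrame(cv_rows) if cv_rows else None,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Variant-site density
# ---------------------------------------------------------------------------

def variant_site_density(
    intervals: IntervalSet, variant_positions: list[tuple[str, int]]
) -> np.ndarray:
    """Per-interval variant sites per bp: VSD_i = #sites in interval / L_i."""
    counts = np.zeros(len(intervals), dtype=np.int64)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in variant_positions}:
        by_chrom[chrom] = np.sort(
            np.asarray([p for c, p in variant_positions if c == chrom], dtype=np.int64)
        )
    for k, iv in enumerate(intervals):
        pos = by_chrom.get(iv.chrom)
        if pos is None:
            continue
        counts[k] = np.searchsorted(pos, iv.end, side="left") - np.searchsorted(
            pos, iv.start, side="left"
        )
    lengths = np.asarray([iv.length for iv in intervals], dtype=float)
    return counts / lengths


def vsd_resampling_test(
    vsd: np.ndarray,
    mf: np.ndarray,
    mf_cutoff: float = 0.4,
    n_resamples: int = 10_000,
    seed: int | None = None,
    alternative: str = "less",
    pooled: bool = False,
    lengths: np.ndarray | None = None,
) -> VSDResamplingResult:
    """Is variant-site density depleted in high-MF intervals?

    Query = intervals with MF > ``mf_cutoff`` (observed statistic: unweighted
    mean of their per-interval VSD, or a pooled count/length rate when
    ``pooled``); null = the same statistic on ``n_resamples`` subsets of
    matching size drawn without replacement from the MF <= cutoff stratum.
    Empirical p uses the +1 correction; ``alternative='less'`` counts null
    means at or below the observation.
    """
    vsd = np.asarray(vsd, dtype=float)
    mf = np.asarray(mf, dtype=float)
    query = mf > mf_cutoff
    background = ~query
    if not query.any() or not background.any():
        raise ValueError("both MF strata must be non-empty")
    k = int(query.sum())
    bg = np.flatnonzero(background)
    if len(bg) < k:
        raise ValueError(f"background ({len(bg)}) smaller than query set ({k})")

    if pooled:
        if lengths is None:
            raise ValueError("pooled mode needs interval lengths")
        lengths = np.asarray(lengths, dtype=float)
        def stat(idx: np.ndarray) -> float:
            return float((vsd[idx] * lengths[idx]).sum() / lengths[idx].sum())
        observed = stat(np.flatnonzero(query))
    else:
        def stat(idx: np.ndarray) -> float:
            return float(vsd[idx].mean())
        observed = stat(np.flatnonzero(query))

    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = bg[rng.choice(len(bg), size=k, replace=False)]
        null[r] = stat(idx)

    if alternative == "less":
        extreme = int((null <= observed).sum())
    elif alternative == "greater":
        extreme = int((null >= observed).sum())
    elif alternative == "two-sided":
        center = null.mean()
        extreme = int((np.abs(null - center) >= abs(observed - center)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + extreme) / (n_resamples + 1)
    return VSDResamplingResult(
        observed_mean_vsd=observed,
        null_means=null,
        n_resamples=n_resamples,
        set_size=k,
        empirical_p=p,
        alternative=alternative,
    )
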