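"""Statistical feature selection.

The workflow mirrors a conservative nonparametric screen:

1. *Normality vote*: fit a one-way ANOVA per feature and test the residuals
   for normality with three tests (Kolmogorov-Smirnov, Anderson-Darling,
   Lilliefors); the majority verdict decides.  Physiological features are
   typically non-normal, which motivates the next step.
2. *Kruskal-Wallis filter*: rank-based H test across the three emotion
   classes; only features with p < 0.05 go forward.
3. *Pairwise tests*: two-sample t tests per class pair (fear-happy,
   fear-neutral, happy-neutral) with one-step Bonferroni correction
   (p multiplied by the number of pairs, clipped at 1), to see which pairs
   each feature separates.
4. *Priority queue*: each pair gets a column of features sorted by
   ascending corrected p; the queue is read row by row across columns,
   within a row ordered by p, duplicates dropped at first occurrence.
5. *Correlation pruning*: a greedy scan in queue order keeps a feature only
   if its absolute Pearson correlation with every already-kept feature is
   below 0.7.

Ties are broken by ascending F-number throughout, making the pipeline
deterministic for a given matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

ALPHA = 0.05
CORR_THRESHOLD = 0.7
#: class pairs for the binary problems, in conventional order
PAIRS = {"FH": ("fear", "happy"), "FN": ("fear", "neutral"),
         "HN": ("happy", "neutral")}


@dataclass
class SelectionReport:
    normality_votes: pd.DataFrame          # per feature: 3 verdicts + majority
    kw_pvalues: pd.Series                  # per feature
    kw_passing: list[str]
    pairwise_pvalues: pd.DataFrame         # feature x {FH, FN, HN}, corrected
    priority_queue: list[str]
    selected: list[str]
    correlation_before: pd.DataFrame = field(default=None)
    correlation_after: pd.DataFrame = field(default=None)

    def validate(self, threshold: float = CORR_THRESHOLD) -> None:
        """Assert the structural invariants of a finished report."""
        assert set(self.selected) <= set(self.priority_queue)
        assert set(self.priority_queue) <= set(self.kw_passing)
        if len(self.selected) > 1:
            c = self.correlation_after.to_numpy()
            off = np.abs(c - np.eye(len(c)))
            assert off.max() < threshold


def _fnum(fid: str) -> tuple:
    """Sort key: numeric F-id when possible, else lexicographic."""
    try:
        return (0, int(str(fid).lstrip("Ff")))
    except ValueError:
        return (1, str(fid))


# ---------------------------------------------------------------------------
# step 1: normality vote
# ---------------------------------------------------------------------------

def normality_vote(values: np.ndarray, labels: np.ndarray,
                   alpha: float = ALPHA) -> dict:
    """Majority verdict of three normality tests on one-way ANOVA residuals.

    Returns a dict with the per-test verdicts (True = normal at ``alpha``)
    and the majority ``verdict`` ("normal" / "non-normal").
    """
    x = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [x[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise ValueError("normality vote needs >= 2 groups with >= 3 "
                         "observations each")
    resid = np.concatenate([g - g.mean() for g in groups])
    sd = resid.std()
    if sd == 0:
        raise ValueError("degenerate feature: residuals are constant")
    z = resid / sd

    ks_p = stats.kstest(z, "norm").pvalue
    try:
        ad_normal = stats.anderson(resid, dist="norm",
                                   method="interpolate").pvalue > alpha
    except TypeError:  # scipy < 1.17: compare to the 5% critical value
        ad = stats.anderson(resid, dist="norm")
        crit = ad.critical_values[list(ad.significance_level).index(5.0)]
        ad_normal = ad.statistic < crit
    lf_p = lilliefors(resid, dist="norm")[1]

    votes = {"kolmogorov_smirnov": bool(ks_p > alpha),
             "anderson_darling": bool(ad_normal),
             "lilliefors": bool(lf_p > alpha)}
    majority = sum(votes.values()) >= 2
    return {**votes, "verdict": "normal" if majority else "non-normal"}


# ---------------------------------------------------------------------------
# step 2: Kruskal-Wallis filter
# ---------------------------------------------------------------------------

def kruskal_filter(df: pd.DataFrame, labels: np.ndarray, alpha: float = ALPHA
                   ) -> tuple[list[str], pd.Series]:
    """Keep features whose tie-corrected Kruskal-Wallis p is below alpha."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 3:
        raise ValueError(f"need 3 emotion classes, found {list(classes)}")
    pvals = {}
    for col in df.columns:
        groups = [df[col].to_numpy()[labels == g] for g in classes]
        try:
            pvals[col] = stats.kruskal(*groups).pvalue
        except ValueError:  # all values identical
            pvals[col] = 1.0
    p = pd.Series(pvals)
    surviving = sorted(p.index[p < alpha], key=_fnum)
    return surviving, p


# ---------------------------------------------------------------------------
# step 3: pairwise tests with Bonferroni correction
# ---------------------------------------------------------------------------

def pairwise_bonferroni(df: pd.DataFrame, labels: np.ndarray,
                        feature_ids: list[str] | None = None) -> pd.DataFrame:
    """Two-sample t per class pair; one-step Bonferroni (x3, clipped at 1)."""
    labels = np.asarray(labels)
    feature_ids = feature_ids if feature_ids is not None else list(df.columns)
    k = len(PAIRS)
    rows = {}
    for fid in feature_ids:
        x = df[fid].to_numpy()
        row = {}
        for pair, (a, b) in PAIRS.items():
            xa, xb = x[labels == a], x[labels == b]
            if xa.size < 2 or xb.size < 2 or (np.std(xa) == 0 and np.std(xb) == 0):
                row[pair] = 1.0
                continue
            p = stats.ttest_ind(xa, xb).pvalue
            row[pair] = min(1.0, float(p) * k) if np.isfinite(p) else 1.0
        rows[fid] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(PAIRS)]


# ---------------------------------------------------------------------------
# step 4: priority queue
# ---------------------------------------------------------------------------

def build_priority_queue(pairwise: pd.DataFrame) -> list[str]:
    """Row-wise traversal of the three p-sorted columns.

    Each pair column is sorted ascending by p; row 1 of every column is
    visited before row 2, and within a row entries are ordered by their
    p-values (ties by F-number); repeated features keep their first slot.
    """
    if pairwise.empty:
        return []
    columns = {}
    for pair in pairwise.columns:
        order = sorted(range(len(pairwise)),
                       key=lambda i: (pairwise[pair].iloc[i],
                                      _fnum(pairwise.index[i])))
        columns[pair] = pairwise[pair].iloc[order]
    queue: list[str] = []
    seen = set()
    depth = len(pairwise)
    for row in range(depth):
        entries = []
        for pair, s in columns.items():
            if row < len(s):
                entries.append((s.iloc[row], _fnum(s.index[row]), s.index[row]))
        for _, _, fid in sorted(entries):
            if fid not in seen:
                seen.add(fid)
                queue.append(fid)
    return queue


# ---------------------------------------------------------------------------
# step 5: correlation pruning
# ---------------------------------------------------------------------------

def correlation_prune(df: pd.DataFrame, queue: list[str],
                      threshold: float = CORR_THRESHOLD
                      ) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Greedy redundancy removal in priority order.

    A feature is kept iff its absolute Pearson correlation with every
    already-kept feature is strictly below ``threshold``.  Returns the
    selected list and the correlation matrices before and after pruning.
    """
    if not queue:
        return [], pd.DataFrame(), pd.DataFrame()
    corr_before = df[queue].corr()
    selected: list[str] = []
    for fid in queue:
        r = corr_before.loc[fid, selected].abs() if selected else pd.Series(dtype=float)
        if (r < threshold).all():
            selected.append(fid)
    corr_after = corr_before.loc[selected, selected]
    return selected, corr_before, corr_after


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def select_features(fm, alpha: float = ALPHA,
                    threshold: float = CORR_THRESHOLD) -> SelectionReport:
    """Run the full selection workflow on a feature matrix.

    Expects condition (non-baseline) observations with three emotion
    labels.  Features are z-scored over the given matrix before the
    pairwise t tests and correlations.
    """
    df = fm.df.copy()
    labels = fm.labels
    mu = df.mean(axis=0)
    sd = df.std(axis=0).replace(0.0, 1.0)
    dfz = (df - mu) / sd

    votes = {}
    for col in df.columns:
        try:
            votes[col] = normality_vote(df[col].to_numpy(), labels, alpha)
        except ValueError:
            votes[col] = {"kolmogorov_smirnov": False, "anderson_darling": False,
                          "lilliefors": False, "verdict": "non-normal"}
    votes_df = pd.DataFrame.from_dict(votes, orient="index")

    surviving, kw_p = kruskal_filter(df, labels, alpha)
    pw = pairwise_bonferroni(dfz, labels, surviving)
    queue = build_priority_queue(pw)
    selected, corr_before, corr_after = correlation_prune(dfz, queue, threshold)

    report = SelectionReport(
        normality_votes=votes_df, kw_pvalues=kw_p, kw_passing=surviving,
        pairwise_pvalues=pw, priority_queue=queue, selected=selected,
        correlation_before=corr_before, correlation_after=corr_after)
    report.validate(threshold)
    return report


def report_to_dict(report: SelectionReport) -> dict:
    return {
        "selected": report.selected,
        "priority_queue": report.priority_queue,
        "kw_pvalues": report.kw_pvalues.to_dict(),
        "pairwise_pvalues": report.pairwise_pvalues.to_dict(orient="index"),
        "normality_verdicts": report.normality_votes["verdict"].to_dict(),
    }
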