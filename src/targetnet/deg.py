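"""Two-group differential-expression screening on log2-scale expression data.

The screen declares a gene differentially expressed when |log2 fold change|
exceeds a threshold *and* the two-sample p-value falls below a significance
cutoff (both strict inequalities).  Two test statistics are offered:

``welch``
    The unequal-variance two-sample t test.

``moderated``
    An empirical-Bayes moderated t: per-gene pooled variances are shrunk
    toward a common prior variance whose strength (prior degrees of freedom)
    and location are estimated by the method of moments on the log sample
    variances, assuming a scaled inverse chi-square prior.  The moderated
    statistic uses the posterior variance and gains the prior degrees of
    freedom, which stabilises small-sample inference.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import TargetNetError

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values with group labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id; values on log2 scale.
    groups : pandas.Series
        Maps every sample id to ``"case"`` or ``"control"``.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("gene ids must be unique; collapse duplicates first")
        missing = set(self.data.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)[:5]}")
        labels = set(self.groups.loc[list(self.data.columns)])
        if not labels <= {CASE, CONTROL}:
            raise ValueError(f"group labels must be 'case'/'control', got {labels}")
        for g in (CASE, CONTROL):
            if int((self.groups.loc[list(self.data.columns)] == g).sum()) < 2:
                raise ValueError(f"group '{g}' needs at least 2 samples")

    @property
    def case_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == CASE]

    @property
    def control_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == CONTROL]

    @classmethod
    def from_tsv(cls, matrix_path, groups_path) -> "ExpressionMatrix":
        """Read a gene x sample TSV plus a two-column (sample, group) label TSV.

        Duplicate gene symbols are collapsed to the highest-mean row.
        """
        data = collapse_duplicate_genes(pd.read_csv(matrix_path, sep="\t", index_col=0))
        g = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(data=data, groups=g.astype(str))

    def quantile_normalize(self) -> "ExpressionMatrix":
        """Force all sample distributions to their common (mean) quantile profile."""
        ranks = self.data.rank(method="average")
        means = np.sort(self.data.values, axis=0).mean(axis=1)
        interp = np.interp(ranks.values, np.arange(1, len(means) + 1), means)
        return ExpressionMatrix(
            data=pd.DataFrame(interp, index=self.data.index, columns=self.data.columns),
            groups=self.groups,
        )


def collapse_duplicate_genes(data: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene symbol, the row with the highest mean expression."""
    if data.index.is_unique:
        return data
    by_mean = np.argsort(-data.mean(axis=1).to_numpy(), kind="stable")
    out = data.iloc[by_mean]
    out = out[~out.index.duplicated(keep="first")]
    return out.reindex(data.index.drop_duplicates())


def read_series_matrix(path) -> pd.DataFrame:
    """Parse the tab-separated data block of a GEO series-matrix text file.

    Only the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; metadata lines are ignored.
    """
    lines: list[str] = []
    inside = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise TargetNetError("no series_matrix table block found")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (trigamma is strictly decreasing)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    return float(
        optimize.brentq(lambda y: special.polygamma(1, y) - x, 1e-8, 1e8, xtol=1e-12)
    )


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square variance prior.

    Returns ``(d0, s0_sq)``: prior degrees of freedom (possibly ``inf``) and
    prior variance.  Works on the log sample variances, whose mean and
    variance under the hierarchical model are analytic in digamma/trigamma
    terms.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 2:
        raise TargetNetError("need at least two genes with positive variance")
    z = np.log(positive)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    emean = float(np.mean(z)) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    if evar > 0:
        d0 = 2.0 * _inv_trigamma(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def test_two_groups(matrix: ExpressionMatrix, method: str = "moderated") -> pd.DataFrame:
    """Per-gene two-group test; returns a table with log2fc, t_stat and p_value.

    ``log2fc`` is case mean minus control mean (data assumed already log2).
    """
    if method not in {"welch", "moderated"}:
        raise ValueError(f"unknown method {method!r}")
    case = matrix.data[matrix.case_columns].to_numpy(dtype=float)
    ctrl = matrix.data[matrix.control_columns].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)

    if method == "welch":
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        bad = ~np.isfinite(p)
        if bad.any():
            logger.warning(
                "%d constant gene(s) under welch: p_value set to 1", int(bad.sum())
            )
            t[bad] = 0.0
            p[bad] = 1.0
    else:
        df = n1 + n2 - 2
        s2 = (case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / df
        d0, s0_sq = _fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_post = 1e9
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_post = df + d0
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = log2fc / se
        p = 2.0 * stats.t.sf(np.abs(t), df_post)

    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t, "p_value": p}, index=matrix.data.index
    )


def flag_degs(
    deg: pd.DataFrame, fc_threshold: float = 1.0, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Annotate a test table with strict-threshold pass flags and direction."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = deg.copy()
    passes = (out["log2fc"].abs() > fc_threshold) & (out["p_value"] < p_threshold)
    out["passes"] = passes
    out["direction"] = np.where(
        passes, np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    return out


def screen_degs(
    deg: pd.DataFrame, fc_threshold: float = 1.0, p_threshold: float = 0.05
) -> tuple[set, set]:
    """Split genes passing |log2fc| > fc_threshold and p < p_threshold into up/down sets."""
    flagged = flag_degs(deg, fc_threshold, p_threshold)
    up = set(flagged.index[flagged["direction"] == "up"])
    down = set(flagged.index[flagged["direction"] == "down"])
    return up, down


def write_deg_tsv(deg: pd.DataFrame, path) -> None:
    flagged = deg if "direction" in deg.columns else flag_degs(deg)
    flagged.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)
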