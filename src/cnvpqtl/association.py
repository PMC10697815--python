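"""Protein normalization and copy-number / protein association testing.

Protein measurements are pre-adjusted for age, sex and batch by ordinary
least squares, then normalized with the rank-based inverse normal transform
(Blom offset 3/8) and standardized so each protein has mean 0 and SD 1
exactly. Each (CNV, protein) pair with at least ``carrier_min`` samples
carrying a copy number different from 2 and an observed protein value is
tested by OLS of the protein on the continuous CN plus the first ``n_pcs``
genetic principal components; significance is Bonferroni over the number of
tests actually performed. Diagnostics cover the genomic inflation factor
(median chi-square method), a Kruskal-Wallis comparison of inflation
between protein groups, and Fisher's exact test for cis/trans enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval

CARRIER_TOL = 1e-9  # |cn - 2| above this counts as a carrier


@dataclass
class AssociationRecord:
    region: str
    protein_id: str
    beta: float
    se: float
    p_value: float
    n_used: int
    n_carriers: int
    n_deleted: int
    n_duplicated: int
    cis_trans: str | None = None


@dataclass
class TestPlan:
    """Bookkeeping of the multiple-testing family actually tested."""

    n_tests_performed: int
    alpha_family: float = 0.05
    carrier_min: int = 3
    n_pcs: int = 4

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.n_tests_performed, self.alpha_family)


def adjust_covariates(
    values: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    batch: pd.Series,
) -> pd.Series:
    """Residualize a protein on age + sex + batch (categorical) by OLS.

    Missing protein values propagate as missing. Terms that make the design
    singular — e.g. a single batch level — are dropped with a warning.
    """
    df = pd.DataFrame({"y": values, "age": age, "sex": sex, "batch": batch})
    obs = df["y"].notna()
    if obs.sum() < 10:
        raise ValueError("need >= 10 non-missing values to adjust covariates")
    cols = [np.ones(int(obs.sum()))]
    names = ["intercept"]
    sub = df.loc[obs]
    for term in ("age", "sex"):
        x = sub[term].to_numpy(dtype=float)
        if np.unique(x).size > 1:
            cols.append(x)
            names.append(term)
        else:
            warnings.warn(f"covariate {term!r} is constant; dropped", stacklevel=2)
    levels = pd.unique(sub["batch"])
    if len(levels) > 1:
        for lev in levels[1:]:  # first level is the reference
            cols.append((sub["batch"] == lev).to_numpy(dtype=float))
            names.append(f"batch[{lev}]")
    else:
        warnings.warn("single batch level; batch term dropped", stacklevel=2)
    X = np.column_stack(cols)
    y = sub["y"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = pd.Series(np.nan, index=values.index, name=values.name)
    resid.loc[obs] = y - X @ beta
    return resid


def inverse_normal_transform(values: pd.Series | np.ndarray) -> pd.Series:
    """Rank-based inverse normal transform, standardized to mean 0 / SD 1.

    Ranks (average rank for ties) are mapped through the standard normal
    quantile at (r - 3/8)/(n + 1/4), then the result is centred and scaled
    by the sample SD (n-1 denominator) so the output moments are exact.
    """
    s = pd.Series(values).astype(float)
    obs = s.notna()
    x = s[obs].to_numpy()
    if x.size < 3:
        raise ValueError("need >= 3 non-missing values")
    if np.unique(x).size == 1:
        raise ValueError("all values tied; no rank information")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
    z = (z - z.mean()) / z.std(ddof=1)
    out = pd.Series(np.nan, index=s.index, name=s.name)
    out[obs] = z
    return out


def normalize_proteins(proteins: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Adjust every protein for age/sex/batch, then inverse-normal transform."""
    out = {}
    for col in proteins.columns:
        resid = adjust_covariates(
            proteins[col], covariates["age"], covariates["sex"], covariates["batch"]
        )
        out[col] = inverse_normal_transform(resid)
    return pd.DataFrame(out, index=proteins.index)


def carrier_mask(cn: np.ndarray) -> np.ndarray:
    return ~np.isnan(cn) & (np.abs(cn - 2.0) > CARRIER_TOL)


def filter_testable(cn: np.ndarray, protein: np.ndarray, carrier_min: int = 3) -> bool:
    """True iff >= carrier_min samples have CN != 2 and an observed protein value."""
    cn = np.asarray(cn, dtype=float)
    protein = np.asarray(protein, dtype=float)
    return int(np.sum(carrier_mask(cn) & ~np.isnan(protein))) >= carrier_min


def _ols_t(X: np.ndarray, y: np.ndarray, coef_idx: int = 1) -> tuple[float, float, float]:
    """OLS beta, SE and two-sided t-test p for one coefficient."""
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough observations for the design")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("singular design")
    resid = y - X @ beta
    df = n - k
    s2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[coef_idx, coef_idx]))
    if se == 0:
        return float(beta[coef_idx]), 0.0, 1.0 if beta[coef_idx] == 0 else np.nextafter(0, 1)
    t = beta[coef_idx] / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(beta[coef_idx]), se, float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def fit_association(
    cn: np.ndarray,
    protein: np.ndarray,
    pcs: np.ndarray | None,
    n_pcs: int = 4,
    region: str = "",
    protein_id: str = "",
    extra_covariates: np.ndarray | None = None,
) -> AssociationRecord:
    """OLS of protein on intercept + CN + the first ``n_pcs`` PCs.

    Missing values are removed listwise. Reports beta/SE and the two-sided
    t-test p-value for the CN coefficient. ``extra_covariates`` supports
    conditional analyses (e.g. SNP allele counts).
    """
    cn = np.asarray(cn, dtype=float)
    protein = np.asarray(protein, dtype=float)
    used = ~np.isnan(cn) & ~np.isnan(protein)
    pc_block = None
    if pcs is not None and n_pcs > 0:
        pc_block = np.asarray(pcs, dtype=float)[:, :n_pcs]
        used &= ~np.isnan(pc_block).any(axis=1)
    extra_block = None
    if extra_covariates is not None:
        extra_block = np.asarray(extra_covariates, dtype=float)
        if extra_block.ndim == 1:
            extra_block = extra_block[:, None]
        if extra_block.shape[0] != cn.size:
            extra_block = extra_block.T
        used &= ~np.isnan(extra_block).any(axis=1)
    x = cn[used]
    if np.unique(x).size < 2:
        raise ValueError("no CN variance among used samples")
    design = [np.ones(int(used.sum())), x]
    if pc_block is not None:
        design.append(pc_block[used])
    if extra_block is not None:
        design.append(extra_block[used])
    X = np.column_stack(design)
    beta, se, p = _ols_t(X, protein[used], coef_idx=1)
    carriers = carrier_mask(cn) & used
    return AssociationRecord(
        region=region,
        protein_id=protein_id,
        beta=beta,
        se=se,
        p_value=p,
        n_used=int(used.sum()),
        n_carriers=int(carriers.sum()),
        n_deleted=int(np.sum(carriers & (cn < 2))),
        n_duplicated=int(np.sum(carriers & (cn > 2))),
    )


def bonferroni_threshold(n_tests: int, alpha_family: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_family / n_tests


def run_association_scan(
    cn_matrix: pd.DataFrame,
    normalized_proteins: pd.DataFrame,
    pcs: pd.DataFrame,
    n_pcs: int = 4,
    carrier_min: int = 3,
    alpha_family: float = 0.05,
) -> tuple[list[AssociationRecord], TestPlan]:
    """Test every testable (CNV, protein) pair; return records and the test plan.

    ``cn_matrix`` has CNV units as rows and samples as columns, sample-aligned
    with ``normalized_proteins`` and ``pcs`` (rows = samples).
    """
    samples = [s for s in normalized_proteins.index if s in cn_matrix.columns]
    if not samples:
        raise ValueError("no samples shared between the CN matrix and proteins")
    cnv = cn_matrix[samples].to_numpy(dtype=float)
    prot = normalized_proteins.loc[samples].to_numpy(dtype=float)
    pcs_arr = pcs.loc[samples].to_numpy(dtype=float)
    records: list[AssociationRecord] = []
    n_tests = 0
    for i, region in enumerate(cn_matrix.index):
        cn = cnv[i]
        carriers = carrier_mask(cn)
        if carriers.sum() < carrier_min:
            continue
        for j, pid in enumerate(normalized_proteins.columns):
            y = prot[:, j]
            if int(np.sum(carriers & ~np.isnan(y))) < carrier_min:
                continue
            n_tests += 1
            try:
                rec = fit_association(cn, y, pcs_arr, n_pcs, region=str(region),
                                      protein_id=str(pid))
            except ValueError:
                continue  # no CN variance after listwise deletion
            records.append(rec)
    plan = TestPlan(n_tests_performed=n_tests, alpha_family=alpha_family,
                    carrier_min=carrier_min, n_pcs=n_pcs)
    return records, plan


def classify_cis_trans(
    window: GenomicInterval,
    gene: GenomicInterval | None,
    max_cis_distance: int = 2_000_000,
) -> str | None:
    """cis iff same chromosome and < 2 Mbp from the protein's coding gene."""
    if gene is None:
        return None
    dist = window.distance_to(gene)
    if dist is None:
        return "trans"
    return "cis" if dist < max_cis_distance else "trans"


def fisher_cis_trans(cnv_cis: int, cnv_trans: int, snp_cis: int, snp_trans: int) -> float:
    """Two-sided Fisher's exact p on the 2x2 cis/trans table.

    Two-sidedness sums all tables whose point hypergeometric probability is
    at most the observed one. A zero margin gives p = 1.
    """
    table = np.array([[cnv_cis, cnv_trans], [snp_cis, snp_trans]])
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Inflation factor: median of the chi-square(1 df) quantiles of the
    p-values divided by the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 20:
        raise ValueError("need >= 20 p-values for a stable lambda")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_MEDIAN_1DF)


def compare_inflation(lambdas_with_hits: np.ndarray, lambdas_without: np.ndarray) -> float:
    """Kruskal-Wallis rank-sum p comparing per-protein inflation between groups."""
    a = np.asarray(lambdas_with_hits, dtype=float)
    b = np.asarray(lambdas_without, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    return float(stats.kruskal(a, b).pvalue)
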