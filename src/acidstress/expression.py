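"""Differential expression on a replicated two-condition log2 matrix.

Gene-wise two-sample t statistics are referenced against a permutation null
built by shuffling condition labels: exact enumeration of all label splits
when that is cheaper than the requested number of permutations, seeded random
draws otherwise. q-values are Benjamini–Hochberg adjusted p-values; a gene is
called differentially expressed when q < 0.05 and |log2 fold change| ≥ 1, the
classic two-fold screen. Signed linear ratios follow the convention of
reporting +2^|FC| for increased and −2^|FC| for decreased abundance.

The packaged reference table (``load_reference_table``) holds the
differentially expressed genes of an E. coli MG1655 octanoic-acid challenge
at 10 mM, pH 7.0 — dominated by induction of the acid-resistance fitness
island (gadB at +25.3-fold) and repression of flagellar/chemotaxis genes and
outer-membrane porins (nmpC at −16.3-fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

__all__ = [
    "ExpressionStudy",
    "median_center",
    "permutation_t_test",
    "fdr_qvalues",
    "fold_changes",
    "signed_ratio",
    "de_analysis",
    "call_significant",
    "table_extremes",
    "load_reference_table",
]

CONTROL, TREATED = "control", "treated"


@dataclass(frozen=True)
class ExpressionStudy:
    """Genes × samples log2-intensity matrix with condition labels.

    ``matrix`` is a DataFrame indexed by gene id; ``conditions`` maps each
    sample column to ``"control"`` or ``"treated"``.
    """

    matrix: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if not set(self.conditions.index) == set(self.matrix.columns):
            raise InvalidInputError("conditions must label exactly the matrix columns")
        if self.matrix.isna().any().any():
            raise InvalidInputError("expression matrix contains missing values")

    def require_two_groups(self) -> None:
        """DE substrate check: control/treated labels with >=2 samples each."""
        labels = set(self.conditions)
        if not labels <= {CONTROL, TREATED}:
            raise InvalidInputError(f"unknown condition labels: {labels}")
        counts = self.conditions.value_counts()
        if counts.get(CONTROL, 0) < 2 or counts.get(TREATED, 0) < 2:
            raise InvalidInputError("need at least 2 samples per condition")

    @property
    def control_samples(self) -> list[str]:
        return list(self.conditions.index[self.conditions == CONTROL])

    @property
    def treated_samples(self) -> list[str]:
        return list(self.conditions.index[self.conditions == TREATED])

    @classmethod
    def from_tsv(cls, matrix_path, samples_path) -> "ExpressionStudy":
        """Load from a matrix TSV (first column gene_id) and a sample sheet
        TSV (columns sample_id, condition)."""
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        cond = pd.Series(
            sheet["condition"].values, index=sheet["sample_id"].astype(str)
        )
        mat.columns = mat.columns.astype(str)
        return cls(matrix=mat, conditions=cond)


def median_center(study: ExpressionStudy) -> ExpressionStudy:
    """Per-sample median centering in log2 space — the normalization-lite
    stand-in used for synthetic inputs (probe-level background correction is
    out of scope here)."""
    centered = study.matrix - study.matrix.median(axis=0)
    return ExpressionStudy(matrix=centered, conditions=study.conditions)


def _t_stats(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Equal-variance two-sample t per row; 0 for fully degenerate rows,
    ±inf when the pooled variance vanishes but means differ."""
    n1, n2 = x.shape[1], y.shape[1]
    diff = x.mean(axis=1) - y.mean(axis=1)
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    sp2 = ss / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        fallback = np.where(diff == 0, 0.0, np.inf * np.sign(diff))
    return np.where(denom == 0, fallback, t)


def permutation_t_test(
    study: ExpressionStudy,
    n_perm: int = 10000,
    seed: int | None = None,
    null: str = "per_gene",
) -> pd.DataFrame:
    """Gene-wise permutation t-test of treated vs control.

    The null distribution permutes condition labels across samples. When the
    number of distinct label assignments C(n, n_treated) is ≤ ``n_perm`` the
    enumeration is exhaustive, otherwise ``n_perm`` seeded random splits are
    drawn.

    Two null constructions:

    * ``"per_gene"`` — each gene is compared against its own permuted
      statistics. Exhaustive p is the exact fraction of splits with
      |t| ≥ |t_observed| (the identity split counts itself, so p ≥ 1/B);
      sampled mode uses the add-one estimator (b+1)/(B+1). With few
      replicates this floor is coarse: 3 vs 3 cannot go below p = 0.1.
    * ``"pooled"`` — permuted |t| values are pooled across *all* genes into
      one null distribution (splits equivalent to the observed labeling are
      excluded; the observed statistic supplies the add-one). Pooling borrows
      the null across the transcriptome, giving the fine-grained p-values
      that few-replicate microarray designs need to reach q < 0.05.

    Genes with zero variance in both groups and equal means get p = 1 and a
    ``degenerate`` flag. Returns a DataFrame indexed by gene with columns
    t, p, degenerate.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    if null not in ("per_gene", "pooled"):
        raise InvalidInputError(f"unknown null construction {null!r}")
    study.require_two_groups()
    data = study.matrix.to_numpy(dtype=float)
    cols = list(study.matrix.columns)
    tr_idx = np.array([cols.index(s) for s in study.treated_samples])
    ct_idx = np.array([cols.index(s) for s in study.control_samples])
    n = len(cols)
    k = len(tr_idx)

    t_obs = _t_stats(data[:, tr_idx], data[:, ct_idx])
    abs_obs = np.abs(t_obs)
    degenerate = (t_obs == 0) & (
        (data[:, tr_idx].var(axis=1, ddof=1) == 0)
        & (data[:, ct_idx].var(axis=1, ddof=1) == 0)
    )

    n_splits = math.comb(n, k)
    all_idx = np.arange(n)
    tol = 1e-12
    observed_sets = {frozenset(tr_idx.tolist())}
    if n == 2 * k:  # the complementary split reproduces |t| exactly
        observed_sets.add(frozenset(ct_idx.tolist()))
    exhaustive = n_splits <= n_perm

    def splits():
        if exhaustive:
            for treat in combinations(range(n), k):
                yield np.array(treat)
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_perm):
                yield rng.permutation(n)[:k]

    if null == "per_gene":
        count = np.zeros(data.shape[0])
        total = 0
        for treat in splits():
            ctrl = np.setdiff1d(all_idx, treat)
            t_null = _t_stats(data[:, treat], data[:, ctrl])
            count += np.abs(t_null) >= abs_obs - tol
            total += 1
        p = count / total if exhaustive else (count + 1.0) / (total + 1.0)
    else:
        pool: list[np.ndarray] = []
        for treat in splits():
            if frozenset(treat.tolist()) in observed_sets:
                continue
            ctrl = np.setdiff1d(all_idx, treat)
            pool.append(np.abs(_t_stats(data[:, treat], data[:, ctrl])))
        null_values = np.sort(np.concatenate(pool))
        n_null = null_values.size
        # count of null |t| >= |t_obs| via the sorted pool
        geq = n_null - np.searchsorted(null_values, abs_obs - tol, side="left")
        p = (geq + 1.0) / (n_null + 1.0)

    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame(
        {"t": t_obs, "p": p, "degenerate": degenerate}, index=study.matrix.index
    )
    out.attrs["exhaustive"] = exhaustive
    out.attrs["null"] = null
    return out


def fdr_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order-free)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_changes(study: ExpressionStudy) -> pd.Series:
    """log2 fold change, treated minus control means (matrix is log2)."""
    study.require_two_groups()
    return (
        study.matrix[study.treated_samples].mean(axis=1)
        - study.matrix[study.control_samples].mean(axis=1)
    )


def signed_ratio(log2_fc: float) -> float:
    """Linear expression ratio with sign encoding direction: +2^|FC| for
    increases, −2^|FC| for decreases."""
    mag = 2.0 ** abs(log2_fc)
    return mag if log2_fc >= 0 else -mag


def de_analysis(
    study: ExpressionStudy,
    n_perm: int = 10000,
    seed: int | None = None,
    q_cut: float = 0.05,
    fc_cut: float = 1.0,
    center: bool = True,
    null: str = "pooled",
) -> pd.DataFrame:
    """Full DE table: log2_fc, ratio, p, q, significant, degenerate.

    Defaults to the pooled permutation null — the construction that makes
    q < 0.05 reachable with typical 3-replicate designs.
    """
    if center:
        study = median_center(study)
    tests = permutation_t_test(study, n_perm=n_perm, seed=seed, null=null)
    fc = fold_changes(study)
    q = fdr_qvalues(tests["p"].to_numpy())
    res = pd.DataFrame(
        {
            "log2_fc": fc,
            "ratio": fc.map(signed_ratio),
            "p": tests["p"],
            "q": q,
            "degenerate": tests["degenerate"],
        },
        index=study.matrix.index,
    )
    res["significant"] = (res["q"] < q_cut) & (res["log2_fc"].abs() >= fc_cut)
    return res


def call_significant(
    results: pd.DataFrame, q_cut: float = 0.05, fc_cut: float = 1.0
) -> pd.DataFrame:
    """Genes with q < q_cut and |log2 FC| ≥ fc_cut (the ≥ is inclusive),
    sorted by ratio magnitude, descending."""
    keep = (results["q"] < q_cut) & (results["log2_fc"].abs() >= fc_cut)
    out = results.loc[keep].copy()
    return out.reindex(out["ratio"].abs().sort_values(ascending=False).index)


def table_extremes(de_table: pd.DataFrame) -> tuple[tuple[str, float], tuple[str, float]]:
    """Largest positive and most negative signed ratios with their genes.

    ``de_table`` needs a ``ratio`` column; gene labels come from a ``gene``
    column when present, else the index.
    """
    if len(de_table) == 0:
        raise InvalidInputError("empty DE table")
    genes = de_table["gene"] if "gene" in de_table.columns else de_table.index.to_series()
    ratios = de_table["ratio"].astype(float)
    imax, imin = ratios.idxmax(), ratios.idxmin()
    return (str(genes.loc[imax]), float(ratios.loc[imax])), (
        str(genes.loc[imin]),
        float(ratios.loc[imin]),
    )


def load_reference_table() -> pd.DataFrame:
    """The packaged C8-challenge DE table (locus, gene, p, q, ratio,
    annotation), sorted by ratio magnitude."""
    with resources.files("acidstress.data").joinpath("c8_de_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
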