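"""Network component analysis (NCA): TF activities from expression + topology.

NCA factorizes a genes × conditions expression log-ratio matrix E as

    E ≈ A · P

where the connectivity matrix A is constrained to the known sparsity pattern
of a transcriptional regulatory network (e.g. RegulonDB TF→gene links) and P
holds the hidden transcription-factor activity (TFA) profiles. Unlike PCA or
ICA, the support constraint makes the decomposition unique — up to a per-TF
diagonal scaling — whenever the topology satisfies the NCA identifiability
criteria: A keeps full column rank, each TF's subnetwork remains full-rank
after removing that TF and its targets, and there are at least as many
conditions as TFs.

The factorization is computed by alternating least squares over the support;
the residual is non-increasing by construction. The scaling freedom is fixed
by normalizing each TF column of A so its largest-magnitude entry is +1
(sign anchored to the topology's majority edge sign when signs are given),
after which activities from different random starts coincide on identifiable
data. ΔTFA between conditions is assessed by a bootstrap over replicate
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "RegulatoryTopology",
    "IdentifiabilityReport",
    "NCAResult",
    "TfaChange",
    "check_identifiability",
    "nca_decompose",
    "delta_tfa",
]


@dataclass(frozen=True)
class RegulatoryTopology:
    """Signed TF→gene edge list and the implied support pattern of A."""

    edges: pd.DataFrame  # columns: tf, gene, sign (+1/-1/0; 0 = unsigned)

    def __post_init__(self) -> None:
        required = {"tf", "gene", "sign"}
        if not required <= set(self.edges.columns):
            raise InvalidInputError("edges need columns tf, gene, sign")
        if self.edges.duplicated(subset=["tf", "gene"]).any():
            raise InvalidInputError("duplicate TF→gene edges")

    @classmethod
    def from_edges(cls, pairs, signs=None) -> "RegulatoryTopology":
        df = pd.DataFrame(pairs, columns=["tf", "gene"])
        df["sign"] = 0 if signs is None else list(signs)
        return cls(edges=df)

    @classmethod
    def from_tsv(cls, path) -> "RegulatoryTopology":
        """Read a RegulonDB-network-style TSV: columns TF, gene[, sign]."""
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        if "sign" not in df.columns:
            df["sign"] = 0
        df["sign"] = df["sign"].map({"+": 1, "-": -1, "0": 0, 1: 1, -1: -1, 0: 0})
        return cls(edges=df[["tf", "gene", "sign"]])

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.edges["gene"].unique())

    def support(self) -> pd.DataFrame:
        """Genes × TFs sign pattern (+1/−1 signed, +1 where unsigned)."""
        sup = pd.DataFrame(0, index=self.genes, columns=self.tfs, dtype=float)
        for _, row in self.edges.iterrows():
            sup.loc[row["gene"], row["tf"]] = row["sign"] if row["sign"] != 0 else 1
        return sup


@dataclass(frozen=True)
class IdentifiabilityReport:
    passed: bool
    issues: tuple[str, ...] = ()
    offending_tfs: tuple[str, ...] = ()


def _support_rank(mask: np.ndarray, rng: np.random.Generator) -> int:
    """Generic (structural-numeric) rank of a support pattern: rank of the
    mask filled with random values, maximized over a few draws."""
    best = 0
    for _ in range(3):
        filled = mask * rng.uniform(0.5, 1.5, size=mask.shape)
        best = max(best, int(np.linalg.matrix_rank(filled)))
        if best == min(mask.shape):
            break
    return best


def check_identifiability(
    topology: RegulatoryTopology, n_conditions: int
) -> IdentifiabilityReport:
    """Check the NCA identifiability criteria for a topology.

    Reports, rather than raises: full column rank of the support, per-TF
    reduced-subnetwork rank (columns with identical target sets fail this),
    every TF having at least one target, and n_conditions ≥ n_TFs.
    """
    issues: list[str] = []
    offenders: set[str] = set()
    sup = topology.support()
    mask = (sup.to_numpy() != 0).astype(float)
    tfs = list(sup.columns)
    n_tf = len(tfs)
    rng = np.random.default_rng(0)

    empty = [tf for tf in tfs if mask[:, tfs.index(tf)].sum() == 0]
    # TFs present in the edge list always have >=1 target; empty columns can
    # only arise from a degenerate support, but check anyway
    for tf in empty:
        issues.append(f"TF {tf} regulates no genes")
        offenders.add(tf)

    if _support_rank(mask, rng) < n_tf:
        issues.append("support pattern is column-rank deficient")
        # name indistinguishable TF pairs where the target sets coincide
        for i in range(n_tf):
            for j in range(i + 1, n_tf):
                if np.array_equal(mask[:, i], mask[:, j]):
                    issues.append(
                        f"TFs {tfs[i]} and {tfs[j]} have identical target sets"
                    )
                    offenders.update((tfs[i], tfs[j]))

    for j, tf in enumerate(tfs):
        rows = mask[:, j] == 0  # genes NOT regulated by this TF
        reduced = np.delete(mask[rows], j, axis=1)
        if n_tf > 1 and _support_rank(reduced, rng) < n_tf - 1:
            issues.append(f"reduced subnetwork of TF {tf} is rank deficient")
            offenders.add(tf)

    if n_conditions < n_tf:
        issues.append(
            f"only {n_conditions} conditions for {n_tf} TFs; P cannot have full row rank"
        )

    return IdentifiabilityReport(
        passed=not issues, issues=tuple(issues), offending_tfs=tuple(sorted(offenders))
    )


@dataclass
class NCAResult:
    A: pd.DataFrame  # genes × TFs, zero off support
    P: pd.DataFrame  # TFs × conditions
    residuals: list[float] = field(default_factory=list)
    converged: bool = False
    excluded_genes: tuple[str, ...] = ()


def _gauge_fix(A: np.ndarray, P: np.ndarray, sup: np.ndarray) -> None:
    """Normalize in place: each TF column's largest-|.| entry becomes +1,
    with the overall column sign anchored to the topology's edge signs when
    provided (majority agreement)."""
    for j in range(A.shape[1]):
        col = A[:, j]
        imax = int(np.argmax(np.abs(col)))
        scale = col[imax]
        if scale == 0:
            continue
        new = col / scale
        signs = sup[:, j]
        if np.any(signs < 0):  # genuinely signed topology
            idx = signs != 0
            agree = np.sum(np.sign(new[idx]) == np.sign(signs[idx]))
            if agree < idx.sum() / 2:
                scale, new = -scale, -new
        A[:, j] = new
        P[j, :] = P[j, :] * scale


def nca_decompose(
    E: pd.DataFrame,
    topology: RegulatoryTopology,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    ridge: float = 1e-8,
    n_starts: int = 5,
) -> NCAResult:
    """Support-constrained alternating least squares for E ≈ A·P.

    P is initialized from standard-normal draws (seeded) and A is solved
    first; each half-step is an exact least-squares solve, so the Frobenius
    residual never increases within a run. The ALS landscape has local
    minima even on identifiable noiseless data, so ``n_starts`` independent
    seeded initializations are run and the lowest-residual solution kept.
    A run stops when the relative residual decrease falls below ``tol`` or
    after ``max_iter`` sweeps. Singular subproblems fall back to a
    ridge-regularized solve with a warning. Genes of E absent from the
    topology are carried in ``excluded_genes`` but not factorized; E must
    cover every topology gene.
    """
    sup_df = topology.support()
    missing = set(sup_df.index) - set(E.index)
    if missing:
        raise InvalidInputError(f"expression matrix lacks topology genes: {sorted(missing)}")
    excluded = tuple(g for g in E.index if g not in set(sup_df.index))
    Es = E.loc[sup_df.index].to_numpy(dtype=float)
    sup = sup_df.to_numpy()
    mask = sup != 0
    n_genes, n_tf = mask.shape
    n_cond = Es.shape[1]

    rng = np.random.default_rng(seed)
    norm_e = np.linalg.norm(Es)
    if norm_e == 0:
        # degenerate: zero expression → zero activities on any support
        A = np.zeros((n_genes, n_tf))
        Pz = np.zeros((n_tf, n_cond))
        return NCAResult(
            A=pd.DataFrame(A, index=sup_df.index, columns=sup_df.columns),
            P=pd.DataFrame(Pz, index=sup_df.columns, columns=E.columns),
            residuals=[0.0],
            converged=True,
            excluded_genes=excluded,
        )

    def solve_ls(M: np.ndarray, y: np.ndarray) -> np.ndarray:
        sol, res_, rank, _ = np.linalg.lstsq(M, y, rcond=None)
        if rank < M.shape[1]:
            warnings.warn("singular NCA subproblem; ridge-regularized", stacklevel=3)
            sol = np.linalg.solve(
                M.T @ M + ridge * np.eye(M.shape[1]), M.T @ y
            )
        return sol

    def als_run(P0: np.ndarray):
        A = np.zeros((n_genes, n_tf))
        P = P0
        residuals: list[float] = []
        converged = False
        for _ in range(max_iter):
            # A-step: per gene, least squares on the active TF columns
            for g in range(n_genes):
                active = mask[g]
                A[g, active] = solve_ls(P[active, :].T, Es[g, :])
            # P-step: global least squares given A
            P = solve_ls(A, Es)
            rel = float(np.linalg.norm(Es - A @ P) / norm_e)
            if residuals and rel > residuals[-1] + 1e-12:
                warnings.warn("ALS residual increased; numerical trouble",
                              stacklevel=2)
            done = bool(residuals) and (residuals[-1] - rel) < tol * max(
                residuals[-1], 1e-300
            )
            residuals.append(rel)
            if done or rel < 1e-13:
                converged = True
                break
        return A, P, residuals, converged

    best = None
    for _ in range(max(1, n_starts)):
        candidate = als_run(rng.standard_normal((n_tf, n_cond)))
        if best is None or candidate[2][-1] < best[2][-1]:
            best = candidate
    A, P, residuals, converged = best

    _gauge_fix(A, P, sup)
    A[~mask] = 0.0
    return NCAResult(
        A=pd.DataFrame(A, index=sup_df.index, columns=sup_df.columns),
        P=pd.DataFrame(P, index=sup_df.columns, columns=E.columns),
        residuals=residuals,
        converged=converged,
        excluded_genes=excluded,
    )


@dataclass(frozen=True)
class TfaChange:
    """Per-TF activity change between conditions with bootstrap significance."""

    tf: str
    delta: float
    direction: str  # "+" or "-"
    p: float | None
    significant: bool


def delta_tfa(
    P: pd.DataFrame,
    condition_labels,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[TfaChange]:
    """ΔTFA = mean(treated) − mean(control) per TF, with an empirical p-value
    from a bootstrap over replicate columns under the no-difference null
    (group-centered resampling). With <2 replicates in a group the p-value is
    omitted and only the magnitude reported.
    """
    labels = pd.Series(list(condition_labels), index=P.columns)
    tr = P.loc[:, labels == "treated"].to_numpy(dtype=float)
    ct = P.loc[:, labels == "control"].to_numpy(dtype=float)
    if tr.shape[1] == 0 or ct.shape[1] == 0:
        raise InvalidInputError("need both control and treated columns")
    delta = tr.mean(axis=1) - ct.mean(axis=1)

    pvals: np.ndarray | None
    if tr.shape[1] >= 2 and ct.shape[1] >= 2:
        rng = np.random.default_rng(seed)
        tr0 = tr - tr.mean(axis=1, keepdims=True)
        ct0 = ct - ct.mean(axis=1, keepdims=True)
        count = np.zeros_like(delta)
        for _ in range(n_boot):
            bt = tr0[:, rng.integers(0, tr.shape[1], tr.shape[1])].mean(axis=1)
            bc = ct0[:, rng.integers(0, ct.shape[1], ct.shape[1])].mean(axis=1)
            count += np.abs(bt - bc) >= np.abs(delta) - 1e-12
        pvals = (count + 1.0) / (n_boot + 1.0)
    else:
        pvals = None

    out = []
    for i, tf in enumerate(P.index):
        p = None if pvals is None else float(pvals[i])
        out.append(
            TfaChange(
                tf=str(tf),
                delta=float(delta[i]),
                direction="+" if delta[i] >= 0 else "-",
                p=p,
                significant=(p is not None and p < alpha),
            )
        )
    return out
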