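"""Cross-probe and cross-compartment statistics.

Implements the statistical layer of the pipeline: Spearman rank correlation
(exact permutation p-values at small n, t-approximation at array scale), the
lncRNA-class × sample length–expression correlation grid, Fisher's exact
2×2 test with the plain cross-product odds ratio, fold-change concordance
between compartments, the triple-compartment DE intersection, correlation-
distance classical (Torgerson) MDS, and average-linkage bi-clustering of the
correlation grid.

Conventions
-----------
* Odds ratio: OR = a·d / (b·c); if b·c = 0 and a·d > 0, OR = +inf; if
  a·d = 0, OR = 0 (no Haldane smoothing unless requested).
* Two-sided Fisher p: sum of hypergeometric probabilities (fixed margins) of
  all tables at most as probable as the observed one.
* Correlation distance: d(i, j) = 1 − Spearman rho, range [0, 2].
* No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import itertools
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.stats import rankdata

GRID_ROWS = ("Total", "Antisense", "Bidirectional", "Sense", "Intergenic")

_ROW_TO_CLASS4 = {
    "Antisense": "antisense_overlap",
    "Bidirectional": "bidirectional",
    "Sense": "sense_overlap",
    "Intergenic": "intergenic",
}


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Spearman rho with two-sided p and sample size; ``reason`` explains an
    absent (NaN) rho or p."""

    rho: float
    p: float
    n: int
    reason: str | None = None

    def is_absent(self) -> bool:
        return not np.isfinite(self.rho)


EXACT_PERMUTATION_MAX_N = 9


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is an exact permutation p (all n! permutations of
    one argument) for n <= 9 and the usual t-approximation above that.  A
    constant input vector leaves rho undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise StatsError("need n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, reason="constant input")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 3:
        return CorrelationResult(rho, float("nan"), n, reason="n < 3")
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return CorrelationResult(rho, p, n)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * sps.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# Length-expression correlation grid (class x sample)
# ---------------------------------------------------------------------------

@dataclass
class CorrelationGrid:
    """lncRNA-class × sample grid of Spearman length–expression results."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def cell(self, row: str, col: str) -> CorrelationResult:
        return CorrelationResult(
            float(self.rho.loc[row, col]),
            float(self.p.loc[row, col]),
            int(self.n.loc[row, col]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: class, sample, rho, p, n."""
        rows = []
        for r in self.rho.index:
            for c in self.rho.columns:
                rows.append((r, c, self.rho.loc[r, c], self.p.loc[r, c], self.n.loc[r, c]))
        return pd.DataFrame(rows, columns=["class", "sample", "rho", "p", "n"])

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def length_expression_grid(expr, lengths: pd.Series, classes: pd.DataFrame) -> CorrelationGrid:
    """Spearman(length, intensity) per collapsed lncRNA class and sample.

    For each sample column, only probes flagged Present/Marginal in that
    sample enter; the Total row pools all classes.  Cells with fewer than
    3 probes are reported absent (NaN).

    Parameters
    ----------
    expr : ExpressionMatrix
    lengths :
        transcript id -> spliced length (bp).
    classes :
        classification table with columns lnc_id, class4.
    """
    class_of = classes.set_index("lnc_id")["class4"]
    tr = expr.probe_transcript
    missing = ~tr.isin(lengths.index)
    if missing.any():
        raise StatsError(f"{int(missing.sum())} probes lack a length (e.g. {tr[missing].iloc[0]!r})")
    missing = ~tr.isin(class_of.index)
    if missing.any():
        raise StatsError(f"{int(missing.sum())} probes lack a class (e.g. {tr[missing].iloc[0]!r})")
    probe_len = lengths.reindex(tr.values).to_numpy(dtype=float)
    probe_cls4 = class_of.reindex(tr.values).to_numpy()

    samples = list(expr.intensity.columns)
    rho = pd.DataFrame(index=list(GRID_ROWS), columns=samples, dtype=float)
    pval = pd.DataFrame(index=list(GRID_ROWS), columns=samples, dtype=float)
    nn = pd.DataFrame(0, index=list(GRID_ROWS), columns=samples, dtype=int)
    for s in samples:
        present = expr.flags[s].isin(("P", "M")).to_numpy()
        inten = expr.intensity[s].to_numpy(dtype=float)
        for row in GRID_ROWS:
            if row == "Total":
                mask = present
            else:
                mask = present & (probe_cls4 == _ROW_TO_CLASS4[row])
            k = int(mask.sum())
            nn.loc[row, s] = k
            if k < 3:
                rho.loc[row, s] = np.nan
                pval.loc[row, s] = np.nan
                continue
            res = spearman_rho(probe_len[mask], inten[mask])
            rho.loc[row, s] = res.rho
            pval.loc[row, s] = res.p
    return CorrelationGrid(rho, pval, nn)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Direction-concordance counts: rows = context-1 up/down, columns =
    context-2 up/down."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise StatsError("contingency cells must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class FisherResult:
    odds_ratio: float
    p_two_sided: float


def odds_ratio(t: ContingencyTable2x2, haldane: bool = False) -> float:
    """Cross-product odds ratio with 0/inf conventions (or +0.5 smoothing)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)
    if a * d == 0:
        return 0.0
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def fisher_exact(t: ContingencyTable2x2, haldane: bool = False) -> FisherResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    p is the sum over all tables with the observed margins whose
    hypergeometric probability does not exceed the observed table's.
    """
    if t.total < 1:
        raise StatsError("all-zero contingency table")
    _, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return FisherResult(odds_ratio(t, haldane=haldane), float(p))


# ---------------------------------------------------------------------------
# Fold-change concordance between two compartments
# ---------------------------------------------------------------------------

def fold_change_concordance(
    deA: pd.DataFrame, deB: pd.DataFrame
) -> tuple[CorrelationResult, ContingencyTable2x2, FisherResult]:
    """Concordance of fold changes between two compartments' DE tables.

    Spearman correlation over log2 fold changes of probes passing the flag
    filter in both compartments; a 2×2 direction table (up/down × up/down)
    over probes called DE in both; Fisher's exact test on that table.
    """
    shared = deA.index.intersection(deB.index)
    a = deA.loc[shared]
    b = deB.loc[shared]
    both_flagged = a["passed_flag_filter"] & b["passed_flag_filter"]
    if int(both_flagged.sum()) < 3:
        raise StatsError("fewer than 3 shared flag-passing probes")
    corr = spearman_rho(
        a.loc[both_flagged, "log2fc"].to_numpy(), b.loc[both_flagged, "log2fc"].to_numpy()
    )
    de_both = a["direction"].isin(("up", "down")) & b["direction"].isin(("up", "down"))
    da = a.loc[de_both, "direction"]
    db = b.loc[de_both, "direction"]
    table = ContingencyTable2x2(
        int(((da == "up") & (db == "up")).sum()),
        int(((da == "up") & (db == "down")).sum()),
        int(((da == "down") & (db == "up")).sum()),
        int(((da == "down") & (db == "down")).sum()),
    )
    fisher = fisher_exact(table) if table.total > 0 else FisherResult(float("nan"), float("nan"))
    return corr, table, fisher


# ---------------------------------------------------------------------------
# Triple-compartment DE intersection
# ---------------------------------------------------------------------------

def intersect_de(
    de_heart: pd.DataFrame,
    de_plasma: pd.DataFrame,
    de_wb: pd.DataFrame,
    classes: pd.DataFrame,
    probe_transcript: pd.Series | None = None,
) -> pd.DataFrame:
    """Probes differentially expressed (up or down) in all three compartments.

    Output columns mirror the published overlap table: lnc_id, class4,
    dir_heart, dir_plasma, dir_whole_blood ('+'/'-'), partner_gene_id.
    """
    cls = classes.set_index("lnc_id")
    sign = {"up": "+", "down": "-"}
    rows = []
    shared = de_heart.index.intersection(de_plasma.index).intersection(de_wb.index)
    for probe in shared:
        dirs = (
            de_heart.loc[probe, "direction"],
            de_plasma.loc[probe, "direction"],
            de_wb.loc[probe, "direction"],
        )
        if all(d in sign for d in dirs):
            lnc = probe_transcript.loc[probe] if probe_transcript is not None else probe
            partner = cls["partner_gene_id"].get(lnc)
            c4 = cls["class4"].get(lnc)
            rows.append((lnc, c4, sign[dirs[0]], sign[dirs[1]], sign[dirs[2]], partner))
    return pd.DataFrame(
        rows,
        columns=["lnc_id", "class4", "dir_heart", "dir_plasma", "dir_whole_blood", "partner_gene_id"],
    )


# ---------------------------------------------------------------------------
# lncRNA-mRNA pair concordance
# ---------------------------------------------------------------------------

@dataclass
class PairConcordance:
    table: ContingencyTable2x2
    fisher: FisherResult
    n_pairs: int


def pair_concordance(
    lnc_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    classes: pd.DataFrame,
    lnc_transcript: pd.Series | None = None,
    mrna_transcript: pd.Series | None = None,
    haldane: bool = False,
) -> dict[str, PairConcordance | None]:
    """Direction concordance of lncRNAs with their partner coding genes.

    For each overlap class (sense_overlap, antisense_overlap collapsed), a
    2×2 of (lnc direction) × (partner mRNA direction) over pairs where both
    members are DE, with the cross-product OR and two-sided Fisher p.
    Classes with no DE pairs map to None.

    ``lnc_transcript``/``mrna_transcript`` map probe ids to transcript/gene
    ids when the DE tables are probe-indexed.
    """
    cls = classes.set_index("lnc_id")
    lnc_ids = (
        lnc_transcript.reindex(lnc_de.index)
        if lnc_transcript is not None
        else pd.Series(lnc_de.index, index=lnc_de.index)
    )
    mrna_dir = mrna_de["direction"]
    if mrna_transcript is not None:
        mrna_dir = mrna_dir.groupby(mrna_transcript.reindex(mrna_de.index)).first()
    out: dict[str, PairConcordance | None] = {}
    for c4 in ("sense_overlap", "antisense_overlap"):
        counts = {"a": 0, "b": 0, "c": 0, "d": 0}
        n_pairs = 0
        members = cls.index[cls["class4"] == c4]
        member_probes = lnc_de.index[lnc_ids.isin(members).values]
        for probe in member_probes:
            ldir = lnc_de.loc[probe, "direction"]
            if ldir not in ("up", "down"):
                continue
            partner = cls.loc[lnc_ids.loc[probe], "partner_gene_id"]
            if partner is None or partner not in mrna_dir.index:
                continue
            mdir = mrna_dir.loc[partner]
            if mdir not in ("up", "down"):
                continue
            n_pairs += 1
            key = {"upup": "a", "updown": "b", "downup": "c", "downdown": "d"}[ldir + mdir]
            counts[key] += 1
        if n_pairs == 0:
            out[c4] = None
            continue
        table = ContingencyTable2x2(**counts)
        out[c4] = PairConcordance(table, fisher_exact(table, haldane=haldane), n_pairs)
    return out


# ---------------------------------------------------------------------------
# Correlation distance + classical MDS
# ---------------------------------------------------------------------------

def correlation_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise d(i, j) = 1 − Spearman rho between columns of *profiles*."""
    cols = list(profiles.columns)
    if len(cols) < 2:
        raise StatsError("need at least 2 columns")
    for c in cols:
        if np.ptp(profiles[c].to_numpy(dtype=float)) == 0:
            raise StatsError(f"constant column {c!r}")
    ranks = profiles.rank()
    corr = np.corrcoef(ranks.to_numpy(dtype=float).T)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=cols, columns=cols)


@dataclass
class MDSEmbedding:
    coords: pd.DataFrame
    eigenvalues: np.ndarray


def classical_mds(D: pd.DataFrame | np.ndarray, k: int = 2) -> MDSEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers −D²/2 and takes the top-k non-negative eigenpairs; the
    embedding is centered at the origin by construction.  If fewer than k
    positive eigenvalues exist, missing coordinates are zero-padded with a
    warning.
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        ids = list(range(M.shape[0]))
    if M.shape[0] != M.shape[1]:
        raise StatsError("distance matrix must be square")
    if not np.allclose(M, M.T):
        raise StatsError("distance matrix must be symmetric")
    if not np.allclose(np.diag(M), 0.0):
        raise StatsError("distance matrix must have zero diagonal")
    if (M < 0).any():
        raise StatsError("distances must be non-negative")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-12 * abs(vals[0]) if vals.size else 0)
    n_pos = int(pos.sum())
    use = min(k, n_pos)
    if use < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {k - use} coordinate(s) with zeros",
            stacklevel=2,
        )
    X = np.zeros((n, k))
    if use:
        X[:, :use] = vecs[:, :use] * np.sqrt(vals[:use])
    coords = pd.DataFrame(X, index=ids, columns=[f"dim{i + 1}" for i in range(k)])
    return MDSEmbedding(coords, vals[:use].copy())


# ---------------------------------------------------------------------------
# Bi-clustering of the correlation grid
# ---------------------------------------------------------------------------

@dataclass
class BiclusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_newick: str
    col_newick: str


def bicluster_grid(grid: CorrelationGrid | pd.DataFrame) -> BiclusterResult:
    """Hierarchically cluster rows and columns of a rho grid.

    Agglomerative average linkage on Euclidean distances over rho values,
    rows and columns independently; scipy's deterministic merge order is the
    tie-break.  Absent (NaN) cells are an error.
    """
    rho = grid.rho if isinstance(grid, CorrelationGrid) else grid
    if rho.isna().any().any():
        cells = [
            f"({r},{c})" for r in rho.index for c in rho.columns if pd.isna(rho.loc[r, c])
        ]
        raise StatsError(f"grid has absent cells: {', '.join(cells)}")
    X = rho.to_numpy(dtype=float)
    row_link = hierarchy.linkage(X, method="average", metric="euclidean")
    col_link = hierarchy.linkage(X.T, method="average", metric="euclidean")
    row_order = [rho.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [rho.columns[i] for i in hierarchy.leaves_list(col_link)]
    return BiclusterResult(
        row_order,
        col_order,
        row_link,
        col_link,
        linkage_to_newick(row_link, list(rho.index)),
        linkage_to_newick(col_link, list(rho.columns)),
    )


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as newick-style nested parentheses."""
    n = len(labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(link[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height(node)
        if node < n:
            return f"{labels[node]}:{bl:.6g}"
        left, right = int(link[node - n, 0]), int(link[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

    root = 2 * n - 2
    h = height(root)
    left, right = int(link[root - n, 0]), int(link[root - n, 1])
    return f"({render(left, h)},{render(right, h)});"


def last_joining_singleton(link: np.ndarray, labels: list[str]) -> str | None:
    """Label of the leaf joined alone in the final merge, if any."""
    n = len(labels)
    a, b = int(link[-1, 0]), int(link[-1, 1])
    if a < n:
        return labels[a]
    if b < n:
        return labels[b]
    return None


def plot_grid_heatmap(
    grid: CorrelationGrid | pd.DataFrame, result: BiclusterResult, path: str | os.PathLike
) -> None:
    """Optional SVG/PNG heatmap of the bi-clustered rho grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rho = grid.rho if isinstance(grid, CorrelationGrid) else grid
    ordered = rho.loc[result.row_order, result.col_order]
    fig, ax = plt.subplots(figsize=(1.2 * len(ordered.columns) + 2, 0.6 * len(ordered) + 2))
    im = ax.imshow(ordered.to_numpy(dtype=float), cmap="RdBu", vmin=-0.3, vmax=0.3, aspect="auto")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(ordered.index)), ordered.index)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
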