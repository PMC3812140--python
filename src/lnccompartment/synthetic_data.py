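"""Synthetic-study generator for the six-array lncRNA compartment design.

Generates everything the pipeline consumes — a coding-gene / lncRNA
annotation whose loci each satisfy exactly one positional-class rule, the
six-array (heart / whole blood / plasma × HF / control) lncRNA and mRNA
expression matrices, qPCR Ct tables — with every statistic the pipeline
computes *planted* at a configured value:

* per-compartment up/down DE counts, exact by construction;
* per-sample, per-class Spearman coupling between lncRNA spliced length and
  intensity (Gaussian copula);
* cross-compartment rank coupling of the heart and plasma log2 fold-change
  vectors;
* lncRNA-mRNA direction-concordance odds ratios per overlap class;
* per-gene true fold changes in the qPCR block.

The planted study profile packaged as ``data/paper_profile.yaml`` encodes the
published study conditions (30k lncRNA probes; heart 518 up / 908 down,
plasma 1619/1582, whole blood 1139/1506; the length-expression correlation
grid; heart-plasma fold coupling −0.24; sense-overlap concordance ORs
4.9 / 2.5 / 4.0).

Copula calibration
------------------
Rank couplings are planted through latent Gaussian variables, converting each
target Spearman ``rho_s`` to the latent Pearson ``2·sin(pi·rho_s/6)``.
Intensities are drawn on the post-normalization scale: every control column is
``log I = mu + sigma·(r·z_len + sqrt(1-r²)·eps)``, and the HF column is the
control column times a planted fold change.  Because the HF sample's own
length coupling must also hit its configured target (the published headline:
the coupling collapses in HF plasma but not elsewhere), the fold-change
latent is itself length-coupled, with the length weight solved per class via
Stein's identity so that the derived HF column lands on its target.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .expression_core import ExpressionMatrix, COMPARTMENTS
from .genome_context import CLASS4, CLASS6, TranscriptModel, collapse_class

_SLOT = 150_000  # genome slot per locus group; isolates classes from each other


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "n_coding",
    "n_lnc",
    "class_mixture",
    "length_distribution",
    "intensity_distribution",
    "flag_absent_rate",
    "length_expr_rho",
    "de_counts",
    "fc_magnitudes",
    "cross_compartment_rho",
    "pair_concordance_or",
    "qpcr",
)


@dataclass
class SimulationConfig:
    """Validated simulation parameters (see ``data/paper_profile.yaml``)."""

    master_seed: int
    n_coding: int
    n_lnc: int
    class_mixture: dict[str, float]
    length_distribution: dict[str, float]
    intensity_distribution: dict[str, float]
    flag_absent_rate: float
    length_expr_rho: dict[str, dict[str, float]]
    de_counts: dict[str, dict[str, int]]
    fc_magnitudes: dict[str, Any]
    cross_compartment_rho: list[dict[str, Any]]
    pair_concordance_or: dict[str, dict[str, float]]
    qpcr: dict[str, Any]
    bidirectional_window_bp: int = 1000
    already_normalized: bool = True

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        for key in _REQUIRED_KEYS:
            if key not in d:
                raise ConfigError(f"missing config key: {key!r}")
        allowed = set(_REQUIRED_KEYS) | {
            "master_seed",
            "bidirectional_window_bp",
            "already_normalized",
        }
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(master_seed=int(d.get("master_seed", 42)), **{k: d[k] for k in _REQUIRED_KEYS},
                   bidirectional_window_bp=int(d.get("bidirectional_window_bp", 1000)),
                   already_normalized=bool(d.get("already_normalized", True)))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def paper_profile(cls, **overrides: Any) -> "SimulationConfig":
        """The packaged study profile, optionally with overridden fields."""
        text = resources.files("lnccompartment.data").joinpath("paper_profile.yaml").read_text()
        d = yaml.safe_load(text)
        d.update(overrides)
        return cls.from_dict(d)

    def validate(self) -> None:
        if set(self.class_mixture) != set(CLASS6):
            raise ConfigError(f"class_mixture must have keys {CLASS6}")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mixture must sum to 1")
        ld = self.length_distribution
        if ld["min_bp"] < 200:
            raise ConfigError("lncRNA lengths must be >= 200 bp")
        for comp, cd in self.de_counts.items():
            if comp not in COMPARTMENTS:
                raise ConfigError(f"unknown compartment {comp!r} in de_counts")
            if cd["up"] + cd["down"] > self.n_lnc:
                raise ConfigError(f"de_counts for {comp} exceed n_lnc")
        for sample, per_class in self.length_expr_rho.items():
            for c4, rho in per_class.items():
                if c4 not in CLASS4:
                    raise ConfigError(f"unknown class {c4!r} in length_expr_rho[{sample}]")
                if abs(rho) > 1:
                    raise ConfigError(f"|rho| > 1 in length_expr_rho[{sample}][{c4}]")
        for entry in self.cross_compartment_rho:
            if abs(entry["rho"]) > 1:
                raise ConfigError("|cross_compartment_rho| > 1")
        if len(self.cross_compartment_rho) > 1:
            raise ConfigError("at most one coupled compartment pair is supported")
        for c4, per_comp in self.pair_concordance_or.items():
            for comp, orv in per_comp.items():
                if orv <= 0:
                    raise ConfigError(f"pair_concordance_or[{c4}][{comp}] must be > 0")
        if not (0 <= self.flag_absent_rate <= 1):
            raise ConfigError("flag_absent_rate must be in [0, 1]")
        n_partnered = round(
            self.n_lnc * (1.0 - self.class_mixture["intergenic"])
        )
        if self.n_coding < n_partnered:
            raise ConfigError(
                f"n_coding={self.n_coding} too small for ~{n_partnered} partnered lncRNAs"
            )


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


def spearman_to_latent(rho_s: float) -> float:
    """Latent Pearson correlation of a Gaussian copula with Spearman rho_s."""
    if abs(rho_s) > 1:
        raise ConfigError(f"|rho_s| must be <= 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _split_exons(rng: np.random.Generator, start: int, total: int, max_exons: int = 3):
    """Exon chain starting at *start* with spliced length *total*."""
    n_ex = int(rng.integers(1, max_exons + 1))
    if total < 100 * n_ex:
        n_ex = 1
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_ex - 1, replace=False)) if n_ex > 1 else []
    sizes = np.diff([0, *cuts, total])
    sizes = np.maximum(sizes, 1)
    sizes[-1] = total - sizes[:-1].sum()
    exons = []
    pos = start
    for i, sz in enumerate(sizes):
        exons.append((pos, pos + int(sz)))
        pos += int(sz)
        if i < len(sizes) - 1:
            pos += int(rng.integers(200, 3000))
    return tuple(exons)


def _draw_lengths(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    ld = cfg.length_distribution
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = np.exp(rng.normal(ld["log_mean"], ld["log_sd"], size=todo.size))
        ok = (draw >= ld["min_bp"]) & (draw <= ld["max_bp"])
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return np.round(out).astype(int)


def generate_annotation(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[list[TranscriptModel], list[TranscriptModel], pd.DataFrame]:
    """Construct coding and lncRNA loci so each lncRNA satisfies exactly its
    intended positional-class rule (and no higher-precedence rule).

    Loci are packed into well-separated genome "slots" (one lncRNA and, where
    the class needs one, its partner gene per slot) so classes cannot collide
    across slots.  Returns (genes, lncs, truth table).
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 1)
    mix = cfg.class_mixture
    counts = {c: int(round(mix[c] * cfg.n_lnc)) for c in CLASS6}
    counts["intergenic"] += cfg.n_lnc - sum(counts.values())  # rounding remainder to the majority class
    class_per_lnc = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(class_per_lnc)
    lengths = _draw_lengths(cfg, rng, cfg.n_lnc)
    window = cfg.bidirectional_window_bp

    genes: list[TranscriptModel] = []
    lncs: list[TranscriptModel] = []
    truth_rows = []
    chrom = "chr1"
    for i in range(cfg.n_lnc):
        cls = str(class_per_lnc[i])
        L = int(lengths[i])
        lnc_id = f"LNC{i:06d}"
        S = i * _SLOT + 10_000
        gene_strand = "+" if rng.random() < 0.5 else "-"
        partner = None
        tss_d = None
        if cls == "intergenic":
            strand = "+" if rng.random() < 0.5 else "-"
            lncs.append(TranscriptModel(lnc_id, chrom, strand, _split_exons(rng, S, L)))
        elif cls in ("sense_overlap", "antisense_overlap"):
            gid = f"GENE{i:06d}"
            g_ex = ((S, S + 1000), (S + 3000, S + 4000), (S + 6000, S + 7000))
            genes.append(TranscriptModel(gid, chrom, gene_strand, g_ex))
            lnc_strand = gene_strand if cls == "sense_overlap" else ("-" if gene_strand == "+" else "+")
            # first lnc exon overlaps the gene's middle exon
            lncs.append(TranscriptModel(lnc_id, chrom, lnc_strand, _split_exons(rng, S + 3500, L)))
            partner = gid
        elif cls in ("intronic", "nonantisense_overlap"):
            gid = f"GENE{i:06d}"
            intron_len = L + 20_000
            g_ex = ((S, S + 500), (S + 500 + intron_len, S + 1000 + intron_len))
            genes.append(TranscriptModel(gid, chrom, gene_strand, g_ex))
            lnc_strand = gene_strand if cls == "intronic" else ("-" if gene_strand == "+" else "+")
            lncs.append(
                TranscriptModel(lnc_id, chrom, lnc_strand, _split_exons(rng, S + 5000, L))
            )
            partner = gid
        elif cls == "bidirectional":
            gid = f"GENE{i:06d}"
            d = int(rng.integers(100, window + 1))
            g_ex = ((S, S + 800), (S + 2000, S + 3000))
            # gene on '-' ends (TSS) at S+3000-1; lnc on '+' starts at TSS+d
            genes.append(TranscriptModel(gid, chrom, "-", g_ex))
            lnc_start = S + 3000 - 1 + d
            lncs.append(TranscriptModel(lnc_id, chrom, "+", _split_exons(rng, lnc_start, L)))
            partner = gid
            tss_d = d
        else:  # pragma: no cover
            raise ConfigError(f"unknown class {cls}")
        truth_rows.append((lnc_id, cls, collapse_class(cls), partner, tss_d, L))

    # free-standing coding genes (no lncRNA partner) fill out the catalog
    n_free = cfg.n_coding - len(genes)
    base = cfg.n_lnc * _SLOT
    for j in range(n_free):
        gid = f"GENEF{j:06d}"
        S = base + j * _SLOT + 10_000
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            TranscriptModel(gid, chrom, strand, ((S, S + 1500), (S + 4000, S + 6000)))
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["lnc_id", "class6", "class4", "partner_gene_id", "tss_distance_bp", "length"],
    )
    return genes, lncs, truth


def sample_probe_truth(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Probe-level truth (class, spliced length) without constructing loci.

    Samples the same class mixture and length distribution as
    :func:`generate_annotation`; useful for copula-calibration studies where
    the genomic geometry is irrelevant.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 1)
    mix = cfg.class_mixture
    counts = {c: int(round(mix[c] * cfg.n_lnc)) for c in CLASS6}
    counts["intergenic"] += cfg.n_lnc - sum(counts.values())
    class_per_lnc = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(class_per_lnc)
    lengths = _draw_lengths(cfg, rng, cfg.n_lnc)
    return pd.DataFrame(
        {
            "lnc_id": [f"LNC{i:06d}" for i in range(cfg.n_lnc)],
            "class6": class_per_lnc,
            "class4": [collapse_class(c) for c in class_per_lnc],
            "partner_gene_id": None,
            "tss_distance_bp": None,
            "length": lengths,
        }
    )


# ---------------------------------------------------------------------------
# Expression (baseline copula draw)
# ---------------------------------------------------------------------------

def _normal_scores(values: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata, norm

    r = rankdata(values, method="average")
    return norm.ppf((r - 0.5) / values.size)


def _draw_flags(rng: np.random.Generator, n: int, absent_rate: float) -> np.ndarray:
    u = rng.random(n)
    flags = np.where(u < absent_rate, "A", np.where(u < absent_rate + 0.85 * (1 - absent_rate), "P", "M"))
    return flags


def _sample_names() -> list[str]:
    return [f"{c}_{g}" for c in COMPARTMENTS for g in ("HF", "control")]


def _samples_frame() -> pd.DataFrame:
    names = _sample_names()
    return pd.DataFrame(
        {
            "compartment": [n.rsplit("_", 1)[0] for n in names],
            "condition": [n.rsplit("_", 1)[1] for n in names],
        },
        index=names,
    )


def generate_expression(
    cfg: SimulationConfig, truth: pd.DataFrame, seed: int | None = None
) -> ExpressionMatrix:
    """Baseline six-column lncRNA expression matrix.

    Each sample column follows a Gaussian copula between length ranks and
    intensity ranks at that sample's per-class configured Spearman target;
    flags are drawn with the configured Absent rate.  Fold-change structure
    is planted afterwards by :func:`plant_fold_changes`.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 2)
    n = len(truth)
    mu = cfg.intensity_distribution["log_mean"]
    sigma = cfg.intensity_distribution["log_sd"]
    z_len = _normal_scores(truth["length"].to_numpy(dtype=float))
    cls4 = truth["class4"].to_numpy()
    intensity = {}
    flags = {}
    for name in _sample_names():
        targets = cfg.length_expr_rho[name]
        r = np.array([spearman_to_latent(targets[c]) for c in cls4])
        eps = rng.normal(size=n)
        logi = mu + sigma * (r * z_len + np.sqrt(1 - r * r) * eps)
        intensity[name] = np.exp(logi)
        flags[name] = _draw_flags(rng, n, cfg.flag_absent_rate)
    probes = pd.Index([f"probe_{l}" for l in truth["lnc_id"]], name="probe_id")
    return ExpressionMatrix(
        pd.DataFrame(intensity, index=probes),
        pd.DataFrame(flags, index=probes),
        pd.Series(truth["lnc_id"].to_numpy(), index=probes, name="transcript_id"),
        _samples_frame(),
    )


# ---------------------------------------------------------------------------
# Fold-change planting
# ---------------------------------------------------------------------------

def _fc_marginal(cfg: SimulationConfig, comp: str, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sorted ln-fold-change marginal for one compartment: n_down planted
    down values, background jitter, n_up planted up values."""
    cd = cfg.de_counts[comp]
    n_up, n_down = int(cd["up"]), int(cd["down"])
    n_bg = n - n_up - n_down
    lo, hi = cfg.fc_magnitudes["up"]
    up = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_up))
    lo, hi = cfg.fc_magnitudes["down"]
    down = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_down))
    b_lo, b_hi = cfg.fc_magnitudes["background_log2"]
    bg = 2.0 ** rng.uniform(b_lo, b_hi, size=n_bg)
    return np.sort(np.log(np.concatenate([down, bg, up])))


def _solve_length_weight(
    sigma: float, r_ctrl: float, r_hf: float, var_m: float, kappa: float
) -> float:
    """Length weight alpha of the fold-change latent for one class.

    Solves (by fixed point) psi = Cov(z_len, lnFC) such that the HF column
    log I_ctrl + lnFC has Pearson r_hf with z_len given the control column's
    r_ctrl, using Cov(log I_ctrl, lnFC) = sigma*r_ctrl*psi (Stein's identity
    for the Gaussian-copula assignment); alpha = psi / kappa.
    """
    psi = 0.0
    for _ in range(60):
        var_hf = sigma * sigma + var_m + 2.0 * sigma * r_ctrl * psi
        psi_new = r_hf * math.sqrt(max(var_hf, 1e-12)) - sigma * r_ctrl
        if abs(psi_new - psi) < 1e-12:
            psi = psi_new
            break
        psi = psi_new
    return psi / kappa


@dataclass
class PlantedTruth:
    """Per-probe planted fold-change structure, one column set per compartment."""

    table: pd.DataFrame  # index probe_id; per comp: lnfc_<comp>, direction_<comp>

    def directions(self, comp: str) -> pd.Series:
        return self.table[f"direction_{comp}"]

    def planted_counts(self, comp: str) -> tuple[int, int]:
        d = self.directions(comp)
        return int((d == "up").sum()), int((d == "down").sum())


def plant_fold_changes(
    cfg: SimulationConfig,
    expr: ExpressionMatrix,
    truth: pd.DataFrame,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Plant per-compartment DE structure into the HF columns.

    For each compartment, every probe receives a multiplicative fold change:
    exactly ``n_up`` probes from the up range, ``n_down`` from the down
    range, the rest background jitter strictly inside the unchanged band.
    Fold-change ranks are assigned through a latent Gaussian that is (a)
    shared between the configured compartment pair at the configured
    cross-compartment coupling and (b) length-coupled per class so the HF
    column still meets its configured length-expression target.  DE is
    planted only among probes whose flags already pass the Present/Marginal
    filter in that compartment, so the filter cannot erode the planted
    counts and flag-filtered subsets remain unbiased samples of every
    planted coupling.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 3)
    n = len(truth)
    sigma = cfg.intensity_distribution["log_sd"]
    z_len = _normal_scores(truth["length"].to_numpy(dtype=float))
    cls4 = truth["class4"].to_numpy()

    # per-compartment sorted marginals and their copula summaries
    marginals = {c: _fc_marginal(cfg, c, rng, n) for c in COMPARTMENTS}
    z_grid = {
        c: np.array([_blom(k, n) for k in range(1, n + 1)]) for c in COMPARTMENTS
    }
    kappa = {c: float(np.mean(marginals[c] * z_grid[c])) for c in COMPARTMENTS}
    var_m = {c: float(np.var(marginals[c])) for c in COMPARTMENTS}

    # per-class length weights alpha
    alpha: dict[str, dict[str, float]] = {}
    for comp in COMPARTMENTS:
        alpha[comp] = {}
        for c4 in CLASS4:
            r_ctrl = spearman_to_latent(cfg.length_expr_rho[f"{comp}_control"][c4])
            r_hf = spearman_to_latent(cfg.length_expr_rho[f"{comp}_HF"][c4])
            alpha[comp][c4] = _solve_length_weight(
                sigma, r_ctrl, r_hf, var_m[comp], kappa[comp]
            )

    # cross-compartment shared factor weights beta (per class, one pair)
    beta: dict[str, dict[str, float]] = {c: {c4: 0.0 for c4 in CLASS4} for c in COMPARTMENTS}
    if cfg.cross_compartment_rho:
        entry = cfg.cross_compartment_rho[0]
        c_a, c_b = entry["pair"]
        r_x = spearman_to_latent(entry["rho"])
        for c4 in CLASS4:
            resid = r_x - alpha[c_a][c4] * alpha[c_b][c4]
            beta[c_a][c4] = math.sqrt(abs(resid))
            beta[c_b][c4] = math.copysign(math.sqrt(abs(resid)), resid)

    u = rng.normal(size=n)  # shared cross-compartment factor
    intensity = expr.intensity.copy()
    cols = {}
    for comp in COMPARTMENTS:
        a = np.array([alpha[comp][c] for c in cls4])
        b = np.array([beta[comp][c] for c in cls4])
        load = a * a + b * b
        if (load > 1).any():
            raise ConfigError(
                f"infeasible coupling for {comp}: |alpha|^2+|beta|^2 > 1; "
                "weaken length_expr_rho contrasts or cross_compartment_rho"
            )
        w = a * z_len + b * u + np.sqrt(1 - load) * rng.normal(size=n)
        hf_col = expr.sample_id(comp, "HF")
        ctrl_col = expr.sample_id(comp, "control")
        # DE is planted only among probes already passing the flag filter, so
        # the flag marginal is undistorted, the filter cannot erode counts,
        # and flag-filtered subsets stay unbiased for every planted coupling
        passing = (
            expr.flags[hf_col].isin(("P", "M")) & expr.flags[ctrl_col].isin(("P", "M"))
        ).to_numpy()
        cd = cfg.de_counts[comp]
        n_up, n_down = int(cd["up"]), int(cd["down"])
        n_pass = int(passing.sum())
        if n_up + n_down > n_pass:
            raise ConfigError(
                f"infeasible de_counts for {comp}: {n_up + n_down} planted probes "
                f"but only {n_pass} flag-passing probes"
            )
        m_sorted = marginals[comp]
        down_vals = m_sorted[:n_down]
        up_vals = m_sorted[n - n_up:]
        bg_vals = m_sorted[n_down : n - n_up]
        lnfc = np.empty(n)
        direction = np.full(n, "unchanged", dtype=object)
        pass_idx = np.flatnonzero(passing)
        fail_idx = np.flatnonzero(~passing)
        pass_sorted = pass_idx[np.argsort(w[pass_idx], kind="stable")]
        fail_sorted = fail_idx[np.argsort(w[fail_idx], kind="stable")]
        n_mid = n_pass - n_up - n_down
        mid_pick = np.sort(rng.choice(bg_vals.size, size=n_mid, replace=False))
        mid_mask = np.zeros(bg_vals.size, dtype=bool)
        mid_mask[mid_pick] = True
        lnfc[pass_sorted] = np.concatenate([down_vals, bg_vals[mid_mask], up_vals])
        lnfc[fail_sorted] = bg_vals[~mid_mask]
        direction[pass_sorted[:n_down]] = "down"
        direction[pass_sorted[n_pass - n_up :]] = "up"
        intensity[hf_col] = intensity[ctrl_col] * np.exp(lnfc)
        cols[f"lnfc_{comp}"] = lnfc
        cols[f"direction_{comp}"] = direction
    planted_truth = PlantedTruth(pd.DataFrame(cols, index=expr.probes))
    out = ExpressionMatrix(
        intensity, expr.flags.copy(), expr.probe_transcript.copy(), expr.samples.copy()
    )
    return out, planted_truth


def _blom(k: int, n: int) -> float:
    from scipy.stats import norm

    return float(norm.ppf((k - 0.375) / (n + 0.25)))


# ---------------------------------------------------------------------------
# mRNA expression for partner genes
# ---------------------------------------------------------------------------

def _concordance_probs(or_target: float) -> tuple[float, float]:
    """P(mRNA up | lnc up) and P(mRNA up | lnc down) with balanced odds
    split: sqrt(OR) on each side, giving the target OR in expectation."""
    s = math.sqrt(or_target)
    return s / (1 + s), 1 / (1 + s)


def generate_mrna_expression(
    cfg: SimulationConfig,
    genes: list[TranscriptModel],
    truth: pd.DataFrame,
    planted: PlantedTruth,
    seed: int | None = None,
) -> ExpressionMatrix:
    """One probe per coding gene; partner genes of DE lncRNAs are forced DE
    with direction drawn from the configured concordance OR for the lncRNA's
    class and compartment, everything else gets background jitter."""
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 4)
    gene_ids = [g.id for g in genes]
    n = len(gene_ids)
    mu = cfg.intensity_distribution["log_mean"]
    sigma = cfg.intensity_distribution["log_sd"]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    partner_rows = truth[truth["partner_gene_id"].notna()]
    lnc_to_gene = dict(zip(partner_rows["lnc_id"], partner_rows["partner_gene_id"]))
    lnc_cls = dict(zip(partner_rows["lnc_id"], partner_rows["class4"]))
    probe_to_lnc = dict(zip(planted.table.index, truth["lnc_id"]))

    b_lo, b_hi = cfg.fc_magnitudes["background_log2"]
    intensity = {}
    flags = {}
    for comp in COMPARTMENTS:
        ctrl = np.exp(rng.normal(mu, sigma, size=n))
        lnfc = np.log(2.0 ** rng.uniform(b_lo, b_hi, size=n))
        comp_flags_hf = _draw_flags(rng, n, cfg.flag_absent_rate)
        comp_flags_ctrl = _draw_flags(rng, n, cfg.flag_absent_rate)
        dirs = planted.directions(comp)
        for probe, ldir in dirs.items():
            if ldir == "unchanged":
                continue
            lnc = probe_to_lnc[probe]
            gene = lnc_to_gene.get(lnc)
            if gene is None:
                continue
            c4 = lnc_cls[lnc]
            or_map = cfg.pair_concordance_or.get(c4)
            if or_map is None or comp not in or_map:
                continue
            p_up_given_up, p_up_given_down = _concordance_probs(or_map[comp])
            p_up = p_up_given_up if ldir == "up" else p_up_given_down
            j = gene_pos[gene]
            if rng.random() < p_up:
                lo, hi = cfg.fc_magnitudes["up"]
            else:
                lo, hi = cfg.fc_magnitudes["down"]
            lnfc[j] = rng.uniform(math.log(lo), math.log(hi))
            comp_flags_hf[j] = "P"
            comp_flags_ctrl[j] = "P"
        intensity[f"{comp}_HF"] = ctrl * np.exp(lnfc)
        intensity[f"{comp}_control"] = ctrl
        flags[f"{comp}_HF"] = comp_flags_hf
        flags[f"{comp}_control"] = comp_flags_ctrl
    probes = pd.Index([f"probe_{g}" for g in gene_ids], name="probe_id")
    order = _sample_names()
    return ExpressionMatrix(
        pd.DataFrame(intensity, index=probes)[order],
        pd.DataFrame(flags, index=probes)[order],
        pd.Series(gene_ids, index=probes, name="transcript_id"),
        _samples_frame(),
    )


def simulate_concordant_pairs(
    or_target: float,
    n_pairs: int,
    seed: int,
    class4: str = "sense_overlap",
    up_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Direction-only DE tables for *n_pairs* lncRNA-mRNA partners whose 2×2
    cell probabilities are solved from *or_target* with balanced margins.

    Returns (lnc_de, mrna_de, classes) ready for
    :func:`lnccompartment.integrative_stats.pair_concordance`.
    """
    rng = _rng(seed, 6)
    p_up_up, p_up_down = _concordance_probs(or_target)
    lnc_dir = np.where(rng.random(n_pairs) < up_fraction, "up", "down")
    p_up = np.where(lnc_dir == "up", p_up_up, p_up_down)
    mrna_dir = np.where(rng.random(n_pairs) < p_up, "up", "down")
    lnc_ids = [f"LNCPAIR{i:05d}" for i in range(n_pairs)]
    gene_ids = [f"GENEPAIR{i:05d}" for i in range(n_pairs)]

    def _de(ids, dirs):
        fc = np.where(dirs == "up", 4.0, 0.25)
        return pd.DataFrame(
            {
                "fc": fc,
                "log2fc": np.log2(fc),
                "direction": dirs,
                "passed_flag_filter": True,
            },
            index=pd.Index(ids, name="probe_id"),
        )

    classes = pd.DataFrame(
        {
            "lnc_id": lnc_ids,
            "class6": class4,
            "class4": class4,
            "partner_gene_id": gene_ids,
            "tss_distance_bp": None,
        }
    )
    return _de(lnc_ids, lnc_dir), _de(gene_ids, mrna_dir), classes


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Long-format Ct table consistent with the configured true fold changes
    under the 2^-ddCt model plus Gaussian Ct noise."""
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 5)
    q = cfg.qpcr
    n_animals = int(q["n_animals"])
    n_rep = int(q.get("n_replicates", 3))
    noise = float(q["ct_noise_sd"])
    reference = q.get("reference", "GAPDH")
    rows = []
    genes = {reference: 1.0, **{g: float(f) for g, f in q["targets"].items()}}
    base_ct = {g: float(rng.uniform(22, 30)) if g != reference else 18.0 for g in genes}
    for group in ("control", "HF"):
        for a in range(n_animals):
            animal = f"{group}_{a + 1:02d}"
            for gene, fold in genes.items():
                true_ct = base_ct[gene] - (math.log2(fold) if group == "HF" else 0.0)
                for _ in range(n_rep):
                    rows.append(
                        (animal, group, gene, true_ct + (rng.normal(0, noise) if noise > 0 else 0.0))
                    )
    return pd.DataFrame(rows, columns=["animal_id", "group", "gene", "ct"])


# ---------------------------------------------------------------------------
# Packaged overlap-table fixture
# ---------------------------------------------------------------------------

def table3_fixture() -> pd.DataFrame:
    """The packaged 32-row transcription of the published triple-compartment
    overlap table (lnc id, relationship with gene, per-compartment direction,
    associated gene id)."""
    with resources.files("lnccompartment.data").joinpath("table3_fixture.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"associated_gene_id": "string"})
    return df


# ---------------------------------------------------------------------------
# Whole-study convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    seed: int
    genes: list[TranscriptModel]
    lncs: list[TranscriptModel]
    truth: pd.DataFrame
    lnc_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    planted: PlantedTruth
    qpcr: pd.DataFrame


def generate_dataset(cfg: SimulationConfig, seed: int | None = None) -> SimulatedStudy:
    """Run every generator stage with substreams of one master seed."""
    seed = cfg.master_seed if seed is None else seed
    genes, lncs, truth = generate_annotation(cfg, seed)
    base = generate_expression(cfg, truth, seed)
    lnc_expr, planted = plant_fold_changes(cfg, base, truth, seed)
    mrna_expr = generate_mrna_expression(cfg, genes, truth, planted, seed)
    qpcr = generate_qpcr(cfg, seed)
    return SimulatedStudy(cfg, seed, genes, lncs, truth, lnc_expr, mrna_expr, planted, qpcr)


def write_simulation(study: SimulatedStudy, outdir: str | os.PathLike) -> dict[str, str]:
    """Write genes.gff3, lncs.gff3, expression TSVs, truth tables and the
    qPCR CSV; returns the path map."""
    from .expression_core import write_expression_table
    from .genome_context import write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genes_gff3": os.path.join(str(outdir), "genes.gff3"),
        "lncs_gff3": os.path.join(str(outdir), "lncs.gff3"),
        "expr_lnc": os.path.join(str(outdir), "expr_lnc.tsv"),
        "expr_mrna": os.path.join(str(outdir), "expr_mrna.tsv"),
        "truth": os.path.join(str(outdir), "truth.tsv"),
        "planted_fc": os.path.join(str(outdir), "planted_fc.tsv"),
        "qpcr": os.path.join(str(outdir), "qpcr.csv"),
    }
    write_gff3(study.genes, paths["genes_gff3"])
    write_gff3(study.lncs, paths["lncs_gff3"])
    write_expression_table(study.lnc_expr, paths["expr_lnc"])
    write_expression_table(study.mrna_expr, paths["expr_mrna"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    study.planted.table.to_csv(paths["planted_fc"], sep="\t")
    study.qpcr.to_csv(paths["qpcr"], index=False)
    return paths
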