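"""Synthetic duodenal-biopsy cohort with the statistical structure the
downstream portrayal analysis assumes.

The generator emulates a 46-sample cohort split into four groups — a disease
control reference (R), a mixed group (M) and two coeliac groups of increasing
severity (CD-L, CD-H) — with:

* five planted co-expression modules (labels A..E) showing group-specific
  activation (A up in R, B in M, C in CD-L, D in CD-L+CD-H, E in CD-H);
* a latent "villous atrophy" score per sample, increasing from R to CD-H,
  onto which modules A and E load with opposite signs (A plays the role of
  the upper-crypt / healthy-villi signature, E the proliferative lower-crypt
  signature);
* an immune-cell mixing layer: per-sample fractions of ``n_cell_types``
  cell types vary along the atrophy score and contribute signature-weighted
  intensity to a dedicated block of marker genes;
* per-sample multiplicative intensity distortions and i.i.d. log2 noise;
* a phenotype table whose serology / Marsh-stage contingency with group
  follows the empirical positivity rates of the study cohort.

Expression is generated in log2 space and exponentiated to a raw intensity
scale, so the preprocessing stage is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

GROUPS = ("R", "M", "CD-L", "CD-H")
MODULE_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: Default 22 immune cell types (bulk-deconvolution convention).
DEFAULT_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

#: Atrophy-dependence of cell-type mixing (log-slope per unit atrophy score);
#: positive = fraction grows with villous atrophy / disease severity.
DEFAULT_MIXING_SLOPES = {
    "T cells CD4 memory activated": 2.0,
    "T cells CD8": 1.5,
    "NK cells activated": 1.0,
    "Macrophages M0": 1.5,
    "Macrophages M1": 2.0,
    "Macrophages M2": -1.5,
    "Dendritic cells resting": -1.5,
    "NK cells resting": -2.0,
}

#: Serology positivity rates per group (R, M, CD-L, CD-H), fixed at the
#: empirical rates of the study cohort.
SEROLOGY_RATES = {
    "IgA_aTTG_pos": (1 / 17, 6 / 9, 8 / 8, 11 / 12),
    "IgA_EmA_pos": (1 / 17, 6 / 9, 8 / 8, 12 / 12),
    "IgG_aDGL_pos": (1 / 17, 4 / 9, 6 / 8, 11 / 12),
}

#: Marsh-stage probabilities per group, empirical cohort proportions.
MARSH_STAGES = ("normal", "1", "2", "3A", "3B/C")
MARSH_PROBS = {
    "R": (15 / 17, 2 / 17, 0.0, 0.0, 0.0),
    "M": (4 / 9, 0.0, 0.0, 4 / 9, 1 / 9),
    "CD-L": (0.0, 0.0, 1 / 8, 2 / 8, 5 / 8),
    "CD-H": (0.0, 0.0, 0.0, 3 / 12, 9 / 12),
}

FEMALE_RATE = {"R": 13 / 17, "M": 6 / 9, "CD-L": 7 / 8, "CD-H": 5 / 12}
AGE_RANGE = {"R": (1, 17), "M": (3, 12), "CD-L": (3, 17), "CD-H": (4, 15)}


def _default_module_effects(n_modules: int, amplitude: float = 1.7,
                            shared_amplitude: float = 0.6) -> np.ndarray:
    """Per-module, per-group mean shifts in log2 units.

    A up in R; B in M; C in CD-L; D in CD-L and CD-H; E in CD-H. Extra
    modules beyond five stay flat. Effects are scaled so every module's
    *centralized* over-expression amplitude (shift times one minus the
    active-sample fraction) is comparable across modules; the shared
    module D is planted at a lower amplitude so that the group-specific
    modules dominate sample-to-sample covariance, as required for the four
    classes to be the discoverable structure.
    """
    eff = np.zeros((n_modules, len(GROUPS)))
    sizes = np.array([17, 9, 8, 12], dtype=float)
    total = sizes.sum()
    pattern = {0: [0], 1: [1], 2: [2], 3: [2, 3], 4: [3]}
    for mod, groups in pattern.items():
        if mod < n_modules:
            active = sizes[groups].sum() / total
            amp = shared_amplitude if len(groups) > 1 else amplitude
            for g in groups:
                eff[mod, g] = amp / (1.0 - active)
    return eff


def _default_gradient_loading(n_modules: int, loading: float = 0.0) -> np.ndarray:
    """Optional extra log2 shift of module genes per unit atrophy score.

    Zero by default: the atrophy gradient is carried by the dedicated
    upper-/lower-crypt blocks, keeping the five spot modules orthogonal
    group indicators.
    """
    load = np.zeros(n_modules)
    if loading != 0.0 and n_modules >= 1:
        load[0] = -loading
    if loading != 0.0 and n_modules >= 5:
        load[4] = loading
    return load


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n_genes: int = 5000
    group_sizes: tuple = (17, 9, 8, 12)
    n_modules: int = 5
    module_size: int = 100
    module_effects: Optional[np.ndarray] = None  # (n_modules, 4) log2 shifts
    gradient_loading: Optional[np.ndarray] = None  # (n_modules,) log2 / unit score
    gradient_range: tuple = ((0.0, 0.3), (0.25, 0.55), (0.5, 0.8), (0.7, 1.0))
    noise_sd: float = 0.5
    sample_scale_sd: float = 0.2
    #: attenuation of the CD-marker module (D) in mixed-group CD samples;
    #: these samples carry real but weaker disease expression, which keeps
    #: single marker genes from separating diagnoses perfectly while their
    #: averaged metagene still can
    mixed_cd_effect_fraction: float = 0.47
    #: two antagonistic gene blocks loaded on the latent atrophy score with
    #: opposite signs: "upper crypt" (healthy villi, decreasing with
    #: atrophy) and "lower crypt" (proliferative, increasing)
    crypt_block_size: int = 80
    crypt_loading: float = 0.75
    baseline_log2: float = 7.0
    baseline_gene_sd: float = 1.0
    n_cell_types: int = 22
    n_marker_genes_per_type: int = 10
    n_shared_immune_genes: int = 30
    immune_scale: float = 25.0
    include_immune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(GROUPS):
            raise ValueError(f"group_sizes must have {len(GROUPS)} entries")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("every group needs at least one sample")
        if self.n_modules > len(MODULE_LABELS):
            raise ValueError("too many modules for single-letter labels")
        n_immune = (
            self.n_cell_types * self.n_marker_genes_per_type
            + self.n_shared_immune_genes
            if self.include_immune
            else 0
        )
        n_structured = (
            self.n_modules * self.module_size + n_immune + 2 * self.crypt_block_size
        )
        if n_structured > self.n_genes:
            raise ValueError(
                f"structured genes exceed n_genes ({n_structured} > {self.n_genes})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.module_effects is None:
            self.module_effects = _default_module_effects(self.n_modules)
        else:
            self.module_effects = np.asarray(self.module_effects, dtype=float)
        if self.module_effects.shape != (self.n_modules, len(GROUPS)):
            raise ValueError("module_effects must be (n_modules, 4)")
        if self.gradient_loading is None:
            self.gradient_loading = _default_gradient_loading(self.n_modules)
        else:
            self.gradient_loading = np.asarray(self.gradient_loading, dtype=float)
        if self.gradient_loading.shape != (self.n_modules,):
            raise ValueError("gradient_loading must be (n_modules,)")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def module_labels(self) -> list:
        return list(MODULE_LABELS[: self.n_modules])


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    module_membership: pd.Series  # gene id -> module label or NaN
    group_labels: pd.Series  # sample id -> group
    atrophy_score: pd.Series  # sample id -> latent lower-crypt activity
    mixing_proportions: Optional[pd.DataFrame]  # samples x cell types
    marker_genes: dict  # {"cd_up": [...], "cd_down": [...]}
    crypt_genes: dict  # {"upper_crypt": [...], "lower_crypt": [...]}
    signature: Optional[pd.DataFrame]  # cohort gene ids x cell types (linear)

    def module_genes(self, label: str) -> list:
        return list(self.module_membership.index[self.module_membership == label])


def simulate_signature_matrix(
    n_marker_genes_per_type: int = 10,
    n_cell_types: int = 22,
    seed: int = 0,
    n_shared_genes: int = 30,
    cell_type_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Linear-scale cell-type signature matrix (genes x cell types).

    Each cell type owns ``n_marker_genes_per_type`` exclusive high-weight
    marker genes; ``n_shared_genes`` background genes are expressed by every
    type. Exclusive markers guarantee full column rank.
    """
    if n_marker_genes_per_type < 1 or n_cell_types < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    if cell_type_names is None:
        if n_cell_types == len(DEFAULT_CELL_TYPES):
            cell_type_names = list(DEFAULT_CELL_TYPES)
        else:
            cell_type_names = [f"CT{i + 1:02d}" for i in range(n_cell_types)]
    n_genes = n_cell_types * n_marker_genes_per_type + n_shared_genes
    s = rng.uniform(0.0, 2.0, size=(n_genes, n_cell_types))  # faint background
    for c in range(n_cell_types):
        rows = slice(c * n_marker_genes_per_type, (c + 1) * n_marker_genes_per_type)
        s[rows, c] = rng.uniform(60.0, 120.0, size=n_marker_genes_per_type)
    shared = slice(n_cell_types * n_marker_genes_per_type, n_genes)
    s[shared, :] = rng.uniform(5.0, 15.0, size=(n_shared_genes, n_cell_types))
    genes = [f"SIG{i + 1:04d}" for i in range(n_genes)]
    return pd.DataFrame(s, index=genes, columns=list(cell_type_names))


def simulate_mixture(
    signature: pd.DataFrame,
    proportions: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Mix signature columns by ``proportions`` with multiplicative
    lognormal noise of coefficient of variation ``noise_cv`` (mean 1)."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    m = signature.to_numpy() @ p
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        m = m * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=m.shape)
    return pd.Series(m, index=signature.index)


def _simulate_mixing_proportions(
    rng: np.random.Generator, atrophy: np.ndarray, cell_types: Sequence[str]
) -> np.ndarray:
    """Per-sample cell fractions whose log-odds drift along the atrophy score."""
    n_types = len(cell_types)
    slopes = np.array([DEFAULT_MIXING_SLOPES.get(ct, 0.0) for ct in cell_types])
    base = rng.lognormal(mean=0.0, sigma=0.4, size=n_types)  # type prevalence
    noise = rng.gamma(shape=8.0, scale=1 / 8.0, size=(len(atrophy), n_types))
    raw = base[None, :] * np.exp(np.outer(atrophy - 0.5, slopes)) * noise
    return raw / raw.sum(axis=1, keepdims=True)


def _simulate_diagnosis(
    rng: np.random.Generator, groups: Sequence[str]
) -> np.ndarray:
    """Diagnosis per sample. R is pure control, CD-L/CD-H pure CD; the
    mixed group gets the cohort's exact composition (5:3:1 CD / control /
    unclear at the default size, proportionally rounded otherwise)."""
    groups = np.asarray(groups)
    diagnosis = np.where(np.isin(groups, ["CD-L", "CD-H"]), "CD", "control").astype(object)
    m_idx = np.flatnonzero(groups == "M")
    n_m = len(m_idx)
    if n_m:
        n_unclear = 1 if n_m >= 3 else 0
        n_cd = int(round(5 / 9 * n_m))
        perm = rng.permutation(m_idx)
        diagnosis[perm[:n_cd]] = "CD"
        diagnosis[perm[n_cd : n_cd + n_unclear]] = "unclear"
        diagnosis[perm[n_cd + n_unclear :]] = "control"
    return diagnosis


def _simulate_phenotypes(
    rng: np.random.Generator,
    sample_ids: Sequence[str],
    groups: Sequence[str],
    diagnosis: Sequence[str],
) -> pd.DataFrame:
    rows = []
    for sid, g, diag in zip(sample_ids, groups, diagnosis):
        gi = GROUPS.index(g)
        row = {
            "sample_id": sid,
            "diagnosis": diag,
            "group": g,
            "marsh": rng.choice(MARSH_STAGES, p=MARSH_PROBS[g]),
            "age": int(rng.integers(AGE_RANGE[g][0], AGE_RANGE[g][1] + 1)),
            "sex": "F" if rng.random() < FEMALE_RATE[g] else "M",
        }
        for col, rates in SEROLOGY_RATES.items():
            row[col] = bool(rng.random() < rates[gi])
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return df[
        ["diagnosis", "group", "IgA_aTTG_pos", "IgA_EmA_pos", "IgG_aDGL_pos",
         "marsh", "age", "sex"]
    ]


def simulate_cohort(
    config: Optional[CohortConfig] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a raw-scale expression matrix, phenotype table and truth.

    Identical configs (including seed) give bit-identical outputs.
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_samples
    groups = np.repeat(list(GROUPS), cfg.group_sizes)
    sample_ids = [f"P{i + 1:02d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    # latent atrophy score per sample, uniform within its group's range
    atrophy = np.empty(n)
    for j, g in enumerate(groups):
        lo, hi = cfg.gradient_range[GROUPS.index(g)]
        atrophy[j] = rng.uniform(lo, hi)

    # gene layout: modules, then immune signature genes, then the two
    # crypt-gradient blocks, then unstructured background
    membership = pd.Series(np.nan, index=gene_ids, dtype=object)
    module_idx = np.full(cfg.n_genes, -1, dtype=int)
    for mod in range(cfg.n_modules):
        sl = slice(mod * cfg.module_size, (mod + 1) * cfg.module_size)
        module_idx[sl] = mod
        membership.iloc[sl] = cfg.module_labels[mod]

    diagnosis = _simulate_diagnosis(rng, groups)
    group_ix = np.array([GROUPS.index(g) for g in groups])

    log2 = np.empty((cfg.n_genes, n))
    baseline = rng.normal(cfg.baseline_log2, cfg.baseline_gene_sd, size=cfg.n_genes)
    # mixed-group CD samples carry the CD-marker module (D) at reduced strength
    mixed_cd = (np.asarray(groups) == "M") & (diagnosis == "CD")
    for g_row in range(cfg.n_genes):
        log2[g_row, :] = baseline[g_row]
        mod = module_idx[g_row]
        if mod >= 0:
            log2[g_row, :] += cfg.module_effects[mod, group_ix]
            log2[g_row, :] += cfg.gradient_loading[mod] * (atrophy - 0.5)
            if mod == 3 and cfg.n_modules >= 4 and mixed_cd.any():
                eff_d = cfg.module_effects[3, GROUPS.index("CD-L")]
                log2[g_row, mixed_cd] += cfg.mixed_cd_effect_fraction * eff_d

    # antagonistic crypt blocks: pure gradient loadings of opposite sign
    n_immune = (
        cfg.n_cell_types * cfg.n_marker_genes_per_type + cfg.n_shared_immune_genes
        if cfg.include_immune
        else 0
    )
    crypt_start = cfg.n_modules * cfg.module_size + n_immune
    upper_rows = slice(crypt_start, crypt_start + cfg.crypt_block_size)
    lower_rows = slice(
        crypt_start + cfg.crypt_block_size, crypt_start + 2 * cfg.crypt_block_size
    )
    log2[upper_rows, :] += -cfg.crypt_loading * (atrophy - 0.5)
    log2[lower_rows, :] += cfg.crypt_loading * (atrophy - 0.5)
    if cfg.noise_sd > 0:
        log2 += rng.normal(0.0, cfg.noise_sd, size=log2.shape)
    if cfg.sample_scale_sd > 0:
        # multiplicative raw-scale distortion == additive log2 offset
        log2 += rng.normal(0.0, cfg.sample_scale_sd, size=(1, n))

    mixing = None
    signature = None
    if cfg.include_immune:
        signature = simulate_signature_matrix(
            cfg.n_marker_genes_per_type,
            cfg.n_cell_types,
            seed=int(rng.integers(2**31)),
            n_shared_genes=cfg.n_shared_immune_genes,
        )
        n_sig = signature.shape[0]
        start = cfg.n_modules * cfg.module_size
        sig_rows = slice(start, start + n_sig)
        # immune marker genes sit on a low epithelial baseline so the mixing
        # layer dominates their intensity
        log2[sig_rows, :] = 4.0 + (log2[sig_rows, :] - baseline[sig_rows, None])
        mixing = _simulate_mixing_proportions(rng, atrophy, signature.columns)
        raw = np.power(2.0, log2)
        raw[sig_rows, :] += cfg.immune_scale * (signature.to_numpy() @ mixing.T)
        signature = pd.DataFrame(
            signature.to_numpy(),
            index=gene_ids[sig_rows.start : sig_rows.stop],
            columns=signature.columns,
        )
        mixing = pd.DataFrame(mixing, index=sample_ids, columns=signature.columns)
    else:
        raw = np.power(2.0, log2)

    em = ExpressionMatrix(
        pd.DataFrame(raw, index=gene_ids, columns=sample_ids), stage="raw"
    )
    phenotype = _simulate_phenotypes(rng, sample_ids, groups, diagnosis)

    labels = cfg.module_labels
    truth = SyntheticTruth(
        module_membership=membership,
        group_labels=pd.Series(groups, index=sample_ids, name="group"),
        atrophy_score=pd.Series(atrophy, index=sample_ids, name="atrophy"),
        mixing_proportions=mixing,
        marker_genes={
            "cd_up": membership.index[membership == "D"].tolist() if "D" in labels else [],
            "cd_down": membership.index[membership == "A"].tolist() if "A" in labels else [],
        },
        crypt_genes={
            "upper_crypt": gene_ids[upper_rows.start : upper_rows.stop],
            "lower_crypt": gene_ids[lower_rows.start : lower_rows.stop],
        },
        signature=signature,
    )
    return em, phenotype, truth


def write_cohort(outdir, em: ExpressionMatrix, phenotype: pd.DataFrame,
                 truth: SyntheticTruth) -> dict:
    """Write expression TSV, phenotype CSV and truth tables; return paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expression.tsv", "phenotype": out / "phenotype.csv"}
    em.to_tsv(paths["expression"])
    phenotype.to_csv(paths["phenotype"])
    paths["module_membership"] = out / "truth_modules.tsv"
    truth.module_membership.rename("module").to_csv(
        paths["module_membership"], sep="\t"
    )
    paths["atrophy"] = out / "truth_atrophy.tsv"
    truth.atrophy_score.to_csv(paths["atrophy"], sep="\t")
    paths["crypt_genes"] = out / "truth_crypt_genes.tsv"
    pd.DataFrame(
        [(g, block) for block, genes in truth.crypt_genes.items() for g in genes],
        columns=["gene_id", "block"],
    ).to_csv(paths["crypt_genes"], sep="\t", index=False)
    if truth.mixing_proportions is not None:
        paths["mixing"] = out / "truth_mixing.tsv"
        truth.mixing_proportions.to_csv(paths["mixing"], sep="\t")
    if truth.signature is not None:
        paths["signature"] = out / "signature.tsv"
        truth.signature.to_csv(paths["signature"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
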