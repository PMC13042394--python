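"""Synthetic crypt-villus sections, cell compositions and TCR repertoires.

The tissue generator lays down a stylized rectilinear jejunum section: a smooth
muscle band along the bottom, a crypt band above it made of discrete
rectangular crypt blocks (one per villus) separated by lamina propria, and
villus columns whose epithelial shell is enterocytes around a lamina propria
core. Immune cell-type labels (CD4T, CD8T, M1, M2, Monocyte, Unclear) are
placed on crypt and lamina propria spots only, with a configurable
multiplicative density enrichment inside the crypt band and an optional
CD8T-M1 co-placement factor that plants spatial co-clustering for the
proximity analysis to recover. Counts are negative binomial with a shared
dispersion; each cell type's marker genes are up-scaled by ``signature_fc`` in
spots of that type, and proliferation genes are up-scaled in crypt-compartment
spots by ``crypt_proliferation_fc``.

Everything is deterministic under ``seed``: the same config yields
byte-identical spot tables and count matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from . import signatures as sigs
from .types import CELL_TYPES, HEADLINE_CELL_TYPES, ValidationError

_IMMUNE_TYPES = HEADLINE_CELL_TYPES  # the five labelled types with planted markers


def _default_fractions() -> dict[str, float]:
    return {"CD4T": 0.03, "CD8T": 0.03, "M1": 0.02, "M2": 0.02, "Monocyte": 0.02}


def _unit_enrichment() -> dict[str, float]:
    return {t: 1.0 for t in _IMMUNE_TYPES}


@dataclass(frozen=True)
class TissueConfig:
    """Parameters of one synthetic section (lengths in µm)."""

    section_width_um: float = 500.0
    section_height_um: float = 250.0
    spot_pitch_um: float = 2.0
    n_villi: int = 6
    crypt_band_um: float = 60.0
    muscle_band_um: float = 30.0
    immune_spot_fraction: dict[str, float] = field(default_factory=_default_fractions)
    crypt_enrichment: dict[str, float] = field(default_factory=_unit_enrichment)
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    signature_fc: float = 4.0
    n_genes: int = 300
    seed: int = 0
    # secondary knobs
    unclear_fraction: float = 0.01
    cd8_m1_coloc: float = 1.0        # M1 placement boost within coloc radius of a crypt CD8T spot
    crypt_proliferation_fc: float = 3.0
    paneth_fraction: float = 0.03
    fibroblast_fraction: float = 0.03
    villus_fill: float = 0.7         # fraction of section width occupied by villi
    condition: str = "generic"

    def validate(self) -> None:
        for name in ("section_width_um", "section_height_um", "spot_pitch_um",
                     "crypt_band_um", "muscle_band_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be positive")
        if self.muscle_band_um + self.crypt_band_um >= self.section_height_um:
            raise ValidationError(
                "muscle_band_um + crypt_band_um: must be < section_height_um"
            )
        if self.n_villi < 1:
            raise ValidationError("n_villi: must be >= 1")
        if set(self.immune_spot_fraction) - set(_IMMUNE_TYPES):
            raise ValidationError("immune_spot_fraction: unknown cell type key")
        for t, f in self.immune_spot_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"immune_spot_fraction[{t}]: must be in [0,1]")
        if sum(self.immune_spot_fraction.values()) > 1.0:
            raise ValidationError("immune_spot_fraction: values must sum to <= 1")
        for t, e in self.crypt_enrichment.items():
            if e < 0:
                raise ValidationError(f"crypt_enrichment[{t}]: must be >= 0")
        if not 0.0 <= self.unclear_fraction <= 1.0:
            raise ValidationError("unclear_fraction: must be in [0,1]")
        if self.cd8_m1_coloc < 0:
            raise ValidationError("cd8_m1_coloc: must be >= 0")
        if not 0.0 < self.villus_fill < 1.0:
            raise ValidationError("villus_fill: must be in (0,1)")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean/nb_dispersion: must be positive")
        if self.signature_fc <= 0 or self.crypt_proliferation_fc <= 0:
            raise ValidationError("signature_fc/crypt_proliferation_fc: must be positive")
        if self.n_genes < len(sigs.ALL_NAMED_GENES):
            raise ValidationError(
                f"n_genes: must be >= {len(sigs.ALL_NAMED_GENES)} (named marker genes)"
            )
        # crypt-zone assignment probabilities (including the co-placement boost)
        # must stay a valid categorical
        crypt_sum = self.unclear_fraction
        for t, f in self.immune_spot_fraction.items():
            boost = self.cd8_m1_coloc if t == "M1" else 1.0
            crypt_sum += f * self.crypt_enrichment.get(t, 1.0) * boost
        if crypt_sum > 1.0:
            raise ValidationError(
                "crypt_enrichment: enriched crypt-zone label probabilities exceed 1"
            )

    def replace(self, **kw) -> "TissueConfig":
        return dataclasses.replace(self, **kw)


def wt_like_tissue(seed: int = 0, **overrides) -> TissueConfig:
    """WT-like condition: M2-dominant crypts, modest CD8 infiltration."""
    cfg = TissueConfig(
        crypt_enrichment={"CD4T": 1.0, "CD8T": 1.5, "M1": 1.0, "M2": 3.0,
                          "Monocyte": 1.0},
        cd8_m1_coloc=1.0,
        crypt_proliferation_fc=3.0,
        condition="WT-like",
        seed=seed,
    )
    return cfg.replace(**overrides) if overrides else cfg


def cko_like_tissue(seed: int = 0, **overrides) -> TissueConfig:
    """cKO-like condition: crypt-enriched CD8T/M1/monocytes, CD8T-M1 co-placement,
    depleted M2 and reduced crypt proliferation."""
    cfg = TissueConfig(
        crypt_enrichment={"CD4T": 1.0, "CD8T": 3.0, "M1": 3.0, "M2": 0.7,
                          "Monocyte": 2.0},
        cd8_m1_coloc=3.0,
        crypt_proliferation_fc=1.0,
        condition="cKO-like",
        seed=seed,
    )
    return cfg.replace(**overrides) if overrides else cfg


def _layout_spots(cfg: TissueConfig) -> pd.DataFrame:
    """Place grid spots and annotate compartments (no immune labels yet)."""
    p = cfg.spot_pitch_um
    ncol = int(cfg.section_width_um // p)
    nrow = int(cfg.section_height_um // p)
    xs = (np.arange(ncol) + 0.5) * p
    ys = (np.arange(nrow) + 0.5) * p
    xg, yg = np.meshgrid(xs, ys)
    x = xg.ravel()
    y = yg.ravel()

    crypt_top = cfg.muscle_band_um + cfg.crypt_band_um
    cell_w = cfg.section_width_um / cfg.n_villi
    villus_w = cfg.villus_fill * cell_w
    centers = (np.arange(cfg.n_villi) + 0.5) * cell_w
    # distance of each spot to its villus column centre (modular in x)
    dx = np.abs((x[:, None] - centers[None, :]))
    dmin = dx.min(axis=1)
    in_column = dmin <= villus_w / 2

    compartment = np.empty(x.size, dtype=object)
    muscle = y < cfg.muscle_band_um
    crypt_band = (y >= cfg.muscle_band_um) & (y < crypt_top)
    villus_zone = y >= crypt_top

    compartment[muscle] = "smooth_muscle"
    compartment[crypt_band & in_column] = "crypt"
    compartment[crypt_band & ~in_column] = "lamina_propria"
    # villus epithelium: a 2-spot shell at the column edge
    shell = villus_w / 2 - dmin <= 2.0 * p
    compartment[villus_zone & in_column & shell] = "enterocyte"
    compartment[villus_zone & in_column & ~shell] = "lamina_propria"
    keep = ~(villus_zone & ~in_column)  # lumen between villi carries no spots

    df = pd.DataFrame(
        {
            "x_um": x[keep],
            "y_um": y[keep],
            "compartment": compartment[keep],
        }
    )
    df.insert(0, "spot_id", [f"spot_{i:06d}" for i in range(len(df))])
    return df


def _sprinkle(rng: np.random.Generator, df: pd.DataFrame, source: str,
              target: str, fraction: float) -> None:
    idx = np.flatnonzero((df["compartment"] == source).to_numpy())
    if idx.size and fraction > 0:
        take = rng.random(idx.size) < fraction
        df.loc[df.index[idx[take]], "compartment"] = target


def _assign_cell_types(rng: np.random.Generator, df: pd.DataFrame,
                       cfg: TissueConfig) -> None:
    """Two-stage label assignment; stage two places M1 with the co-placement boost."""
    eligible = df["compartment"].isin(["crypt", "lamina_propria"]).to_numpy()
    in_crypt_zone = (
        (df["y_um"].to_numpy() >= cfg.muscle_band_um)
        & (df["y_um"].to_numpy() < cfg.muscle_band_um + cfg.crypt_band_um)
    )
    n = len(df)
    labels = np.full(n, "", dtype=object)

    stage1 = [t for t in _IMMUNE_TYPES if t != "M1"] + ["Unclear"]
    probs = np.zeros((n, len(stage1) + 1))
    for k, t in enumerate(stage1):
        base = (cfg.unclear_fraction if t == "Unclear"
                else cfg.immune_spot_fraction.get(t, 0.0))
        enrich = 1.0 if t == "Unclear" else cfg.crypt_enrichment.get(t, 1.0)
        pvec = np.where(in_crypt_zone, base * enrich, base)
        probs[:, k] = np.where(eligible, pvec, 0.0)
    probs[:, -1] = 1.0 - probs[:, :-1].sum(axis=1)
    draw = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    choice = (draw[:, None] >= cum).sum(axis=1)  # index of sampled category
    for k, t in enumerate(stage1):
        labels[choice == k] = t

    # stage 2: M1 among still-unlabelled eligible spots
    p_m1 = cfg.immune_spot_fraction.get("M1", 0.0)
    enrich_m1 = cfg.crypt_enrichment.get("M1", 1.0)
    pvec = np.where(in_crypt_zone, p_m1 * enrich_m1, p_m1)
    if cfg.cd8_m1_coloc != 1.0 and p_m1 > 0:
        cd8 = np.flatnonzero((labels == "CD8T") & in_crypt_zone)
        if cd8.size:
            pts = df[["x_um", "y_um"]].to_numpy()
            tree = cKDTree(pts[cd8])
            dist, _ = tree.query(pts, k=1)
            # boost acts on the 8-neighbourhood of crypt CD8T spots: a tight
            # radius keeps the planted co-clustering local
            near = (dist <= 1.5 * cfg.spot_pitch_um) & in_crypt_zone
            pvec = np.where(near, pvec * cfg.cd8_m1_coloc, pvec)
    open_spot = eligible & (labels == "")
    take = open_spot & (rng.random(n) < np.clip(pvec, 0.0, 1.0))
    labels[take] = "M1"
    df["cell_type"] = labels


def _draw_counts(rng: np.random.Generator, df: pd.DataFrame,
                 cfg: TissueConfig) -> ad.AnnData:
    named = list(sigs.ALL_NAMED_GENES)
    genes = named + [f"G{i:04d}" for i in range(cfg.n_genes - len(named))]
    gene_idx = {g: j for j, g in enumerate(genes)}

    mu = np.full((len(df), cfg.n_genes), cfg.nb_mean)
    for t, sig in sigs.CELL_TYPE_SIGNATURES.items():
        rows = np.flatnonzero((df["cell_type"] == t).to_numpy())
        if rows.size:
            cols = [gene_idx[g] for g in sorted(sig.genes)]
            mu[np.ix_(rows, cols)] *= cfg.signature_fc
    crypt_rows = np.flatnonzero((df["compartment"] == "crypt").to_numpy())
    if crypt_rows.size:
        cols = [gene_idx[g] for g in sorted(sigs.PROLIFERATION.genes)]
        mu[np.ix_(crypt_rows, cols)] *= cfg.crypt_proliferation_fc

    # NB(mean mu, size r) drawn as a gamma-Poisson mixture (fast and vectorized)
    r = cfg.nb_dispersion
    counts = rng.poisson(rng.gamma(r, mu / r)).astype(np.int32)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=pd.Index(df["spot_id"], name="spot_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.uns["norm_state"] = "raw"
    return adata


def simulate_section(cfg: TissueConfig) -> tuple[pd.DataFrame, ad.AnnData, dict]:
    """Generate one annotated section with counts and the planted ground truth.

    Returns
    -------
    spots : DataFrame with columns spot_id, x_um, y_um, compartment, cell_type
        (empty string = no immune label).
    counts : AnnData, raw NB counts, obs indexed by spot_id.
    ground_truth : dict of planted parameters and realized label densities.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spots = _layout_spots(cfg)
    _sprinkle(rng, spots, "crypt", "paneth", cfg.paneth_fraction)
    _sprinkle(rng, spots, "lamina_propria", "fibroblast", cfg.fibroblast_fraction)
    _assign_cell_types(rng, spots, cfg)
    counts = _draw_counts(rng, spots, cfg)

    in_zone = (
        (spots["y_um"] >= cfg.muscle_band_um)
        & (spots["y_um"] < cfg.muscle_band_um + cfg.crypt_band_um)
    )
    eligible = spots["compartment"].isin(["crypt", "lamina_propria"])
    densities = {}
    for t in CELL_TYPES:
        lab = spots["cell_type"] == t
        n_in = int((eligible & in_zone).sum())
        n_out = int((eligible & ~in_zone).sum())
        densities[t] = {
            "crypt_zone": float((lab & eligible & in_zone).sum() / n_in) if n_in else 0.0,
            "outside": float((lab & eligible & ~in_zone).sum() / n_out) if n_out else 0.0,
        }
    ground_truth = {
        "condition": cfg.condition,
        "config": dataclasses.asdict(cfg),
        "n_spots": int(len(spots)),
        "realized_density": densities,
        "planted": {
            "crypt_enrichment": dict(cfg.crypt_enrichment),
            "cd8_m1_coloc": cfg.cd8_m1_coloc,
            "signature_fc": cfg.signature_fc,
            "crypt_proliferation_fc": cfg.crypt_proliferation_fc,
        },
    }
    return spots, counts, ground_truth


# ---------------------------------------------------------------------------
# cell composition tables (for Ro/e)
# ---------------------------------------------------------------------------

def simulate_composition(
    n_per_sample: dict[str, int],
    subset_probs: dict[str, dict[str, float]],
    sample_groups: dict[str, str],
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial cell-composition draws per sample.

    ``subset_probs`` maps group -> {subset: probability}; each sample draws its
    cells from its group's probability vector. Probabilities must sum to 1
    (tolerance 1e-9).
    """
    if not n_per_sample:
        raise ValidationError("n_per_sample: must be non-empty")
    for g, probs in subset_probs.items():
        tot = sum(probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"subset_probs[{g}]: probabilities sum to {tot}, not 1")
        if any(p < 0 for p in probs.values()):
            raise ValidationError(f"subset_probs[{g}]: negative probability")
    rng = np.random.default_rng(seed)
    frames = []
    for sample in sorted(n_per_sample):
        group = sample_groups.get(sample)
        if group not in subset_probs:
            raise ValidationError(f"sample_groups[{sample}]: unknown group {group!r}")
        probs = subset_probs[group]
        subsets = sorted(probs)
        n = n_per_sample[sample]
        if n == 0:
            continue
        counts = rng.multinomial(n, [probs[s] for s in subsets])
        subset_col = np.repeat(subsets, counts)
        frames.append(pd.DataFrame({
            "cell_id": [f"{sample}_cell{i:06d}" for i in range(n)],
            "sample": sample,
            "group": group,
            "subset": subset_col,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# TCR repertoires
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepertoireConfig:
    """Parameters of one sample's synthetic TCR repertoire.

    ``expansion_prob`` is the per-cell probability of joining an expanded clone
    (per subset); expanded clone sizes follow ``expanded_clone_size_dist``,
    either ``("geometric", mean)`` (sizes 1 + Geom, all >= 2) or
    ``("fixed", k)``. Non-expanded cells are singleton clonotypes.
    """

    n_cells_per_subset: dict[str, int]
    expansion_prob: dict[str, float]
    expanded_clone_size_dist: tuple[str, float] = ("geometric", 4.0)
    sample: str = "S1"
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells_per_subset:
            raise ValidationError("n_cells_per_subset: must be non-empty")
        for s, n in self.n_cells_per_subset.items():
            if n < 0:
                raise ValidationError(f"n_cells_per_subset[{s}]: must be >= 0")
        for s, p in self.expansion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"expansion_prob[{s}]: must be in [0,1]")
        kind, par = self.expanded_clone_size_dist
        if kind == "geometric":
            if par < 2.0:
                raise ValidationError(
                    "expanded_clone_size_dist: geometric mean must be >= 2"
                )
        elif kind == "fixed":
            if int(par) < 1:
                raise ValidationError("expanded_clone_size_dist: fixed size must be >= 1")
        else:
            raise ValidationError(
                f"expanded_clone_size_dist: unknown kind {kind!r}"
            )


def _clone_sizes(rng: np.random.Generator, n_cells: int,
                 dist: tuple[str, float]) -> list[int]:
    """Expanded-clone sizes covering exactly ``n_cells`` cells."""
    kind, par = dist
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        if kind == "fixed":
            s = int(par)
        else:  # geometric, mean = par, support >= 2
            s = 1 + int(rng.geometric(1.0 / (par - 1.0)))
        s = min(s, n_cells - total)
        sizes.append(s)
        total += s
    return sizes


def simulate_repertoire(cfg: RepertoireConfig) -> pd.DataFrame:
    """One sample's clonotype table (cell_id, clonotype_id, subset, sample)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for subset in sorted(cfg.n_cells_per_subset):
        n = cfg.n_cells_per_subset[subset]
        p = cfg.expansion_prob.get(subset, 0.0)
        expanded = rng.random(n) < p
        n_exp = int(expanded.sum())
        clone_of = np.full(n, "", dtype=object)
        if n_exp:
            sizes = _clone_sizes(rng, n_exp, cfg.expanded_clone_size_dist)
            ids = np.repeat(
                [f"{cfg.sample}_{subset}_e{j:04d}" for j in range(len(sizes))], sizes
            )
            clone_of[np.flatnonzero(expanded)] = ids
        singles = np.flatnonzero(~expanded)
        for j, i in enumerate(singles):
            clone_of[i] = f"{cfg.sample}_{subset}_s{j:05d}"
        for i in range(n):
            rows.append(
                (f"{cfg.sample}_{subset}_cell{i:05d}", clone_of[i], subset, cfg.sample)
            )
    return pd.DataFrame(rows, columns=["cell_id", "clonotype_id", "subset", "sample"])


_REPERTOIRE_SUBSETS = {"CD4_Tn": 3000, "CD4_Tem": 1500, "CD8_Tn": 2000,
                       "CD8_Tem": 1200, "CD8_Teff": 1500, "Treg": 800}


def wt_like_repertoire(seed: int = 0, sample: str = "WT_1") -> RepertoireConfig:
    """Mostly-unique clonotypes in every subset."""
    return RepertoireConfig(
        n_cells_per_subset=dict(_REPERTOIRE_SUBSETS),
        expansion_prob={s: 0.05 for s in _REPERTOIRE_SUBSETS},
        sample=sample,
        seed=seed,
    )


def cko_like_repertoire(seed: int = 0, sample: str = "cKO_1") -> RepertoireConfig:
    """Targeted clonal expansion of CD8 effector T cells."""
    probs = {s: 0.05 for s in _REPERTOIRE_SUBSETS}
    probs["CD8_Teff"] = 0.3
    return RepertoireConfig(
        n_cells_per_subset=dict(_REPERTOIRE_SUBSETS),
        expansion_prob=probs,
        sample=sample,
        seed=seed,
    )
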