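"""Default marker gene sets for polarization scoring and positive-rate panels.

The shipped M1/M2 sets are the classical pro-inflammatory vs tissue-reparative
macrophage markers used in murine intestinal GVHD work (NF-kB subunits, Fc
receptor and MHC-II genes for M1; TGF-beta and lipid/scavenger genes for M2).
They are defaults, not dogma: any GMT file can replace them.
"""

from __future__ import annotations

from .types import GeneSignature

M1_GENES = ("Nfkb1", "Rela", "Fcgr1", "Cd80", "Cd86", "H2-Aa", "H2-Ab1")
M2_GENES = ("Tgfb1", "Fabp4", "Mrc1", "Aldoa", "Adgre4", "Smad3", "Trem2")

#: Cell-cycle / proliferation genes used for crypt regenerative-capacity rates.
PROLIFERATION_GENES = (
    "Mki67", "Top2a", "Pcna", "Mcm2", "Mcm5", "Rrm2",
    "Tyms", "Ccna2", "Ccnb2", "Cdk1", "Plk1", "Aurkb",
)

#: Effector / exhaustion / residency genes of infiltrating CD8 T cells.
CD8_EFFECTOR_GENES = ("Cd8a", "Gzma", "Gzmb", "Pdcd1", "Tox", "Itgae", "Itga4")

CD4_GENES = ("Cd4", "Tnfsf4", "Epas1", "Ramp3")
MONOCYTE_GENES = ("Cd14", "Ccr2", "Ly6c2", "Ccr1")

DEFAULT_M1 = GeneSignature.from_iterable("M1", M1_GENES)
DEFAULT_M2 = GeneSignature.from_iterable("M2", M2_GENES)
PROLIFERATION = GeneSignature.from_iterable("proliferation", PROLIFERATION_GENES)

#: Per-cell-type marker sets the synthetic generator plants and scoring recovers.
CELL_TYPE_SIGNATURES: dict[str, GeneSignature] = {
    "CD4T": GeneSignature.from_iterable("CD4T", CD4_GENES),
    "CD8T": GeneSignature.from_iterable("CD8T", CD8_EFFECTOR_GENES),
    "M1": DEFAULT_M1,
    "M2": DEFAULT_M2,
    "Monocyte": GeneSignature.from_iterable("Monocyte", MONOCYTE_GENES),
}

#: Every named gene the generator places in the synthetic gene universe.
ALL_NAMED_GENES: tuple[str, ...] = tuple(
    dict.fromkeys(
        gene
        for sig in (*CELL_TYPE_SIGNATURES.values(), PROLIFERATION)
        for gene in sorted(sig.genes)
    )
)
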