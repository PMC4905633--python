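"""Published primer panel for MHC class I exon 2 genotyping in felids.

The panel targets the antigen-binding-domain exon of the Iberian lynx MHC
class I multigene family and realizes the three amplification strategies this
package analyses:

* ``conventional`` -- one highly degenerate pair in a single PCR;
* ``pooled_pcrs``  -- two forward and three reverse low-degeneracy primers
  combined into four primer pairs run in separate PCRs whose products are
  pooled for sequencing in proportion to the number of loci each pair is
  expected to amplify;
* ``pooled_primers`` -- five forward and seven reverse non-degenerate primers
  mixed in a single reaction, each at a concentration proportional to the
  number of flank haplotypes it targets.

The integer weights behind the pool percentages are the reconstructions
consistent with the published concentrations (5:2:2:1:1 forward and
5:2:1:1:1:1:1 reverse for the pooled-primers mix; 3:1:1:1 across the four
pooled PCRs).
"""

from __future__ import annotations

from .primers import (
    CONVENTIONAL,
    FORWARD,
    POOLED_PCRS,
    POOLED_PRIMERS,
    REVERSE,
    DegeneratePrimer,
    PCRAssay,
    PrimerPool,
)

# conventional strategy: one degenerate pair
CONVENTIONAL_F = DegeneratePrimer(
    "Fel_MhcI_ex2_single_F", "f", "GCTCCCAYTCCYTGAKGTAT", FORWARD, CONVENTIONAL
)
CONVENTIONAL_R = DegeneratePrimer(
    "Fel_MhcI_ex2_single_R", "r", "GGMYTCGCTCTGGTTGTAGT", REVERSE, CONVENTIONAL
)

# pooled-PCRs strategy: low-degeneracy primers combined into four pairs
POOLED_PCRS_F1 = DegeneratePrimer(
    "Fel_MhcI_ex2_F1", "f1", "GCTCCCACTCCCTSAGGTAT", FORWARD, POOLED_PCRS
)
POOLED_PCRS_F2 = DegeneratePrimer(
    "Fel_MhcI_ex2_F2", "f2", "GCTCCCAYTCCTTGAKGTAT", FORWARD, POOLED_PCRS
)
POOLED_PCRS_R1 = DegeneratePrimer(
    "Fel_MhcI_ex2_R1", "r1", "GGMYTCGCTCTGGTTGTAGT", REVERSE, POOLED_PCRS
)
POOLED_PCRS_R2 = DegeneratePrimer(
    "Fel_MhcI_ex2_R2", "r2", "GGAAYCGCTCTGGTTGTAGT", REVERSE, POOLED_PCRS
)
POOLED_PCRS_R3 = DegeneratePrimer(
    "Fel_MhcI_ex2_R3", "r3", "SGACWCGCTYTGRTTGTAGT", REVERSE, POOLED_PCRS
)

# pooled-primers strategy: non-degenerate primers at weighted concentrations
POOLED_PRIMERS_F = [
    DegeneratePrimer("Fel_MhcI_ex2_Fa", "fa", "GCTCCCACTCCCTGAGGTAT", FORWARD, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Fb", "fb", "GCTCCCATTCCTTGATGTAT", FORWARD, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Fc", "fc", "GCTCCCACTCCCTCAGGTAT", FORWARD, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Fd", "fd", "GCTCCCACTCCCTGCGGTAT", FORWARD, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Fe", "fe", "GCTCCCACTCCTTGAGGTAT", FORWARD, POOLED_PRIMERS),
]
POOLED_PRIMERS_R = [
    DegeneratePrimer("Fel_MhcI_ex2_Ra", "ra", "GGACTCGCTCTGGTTGTAGT", REVERSE, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Rb", "rb", "GGCTTCGCTCTGGTTGTAGT", REVERSE, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Rc", "rc", "GGACACGCTTTGATTGTAGT", REVERSE, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Rd", "rd", "GGACTCGCTTTGGTTGTAGT", REVERSE, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Re", "re", "GGAATCGCTCTGGTTGTAGT", REVERSE, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Rf", "rf", "CGACTCGCTCTGGTTGTAGT", REVERSE, POOLED_PRIMERS),
    DegeneratePrimer("Fel_MhcI_ex2_Rg", "rg", "GGAACCGCTCTGGTTGTAGT", REVERSE, POOLED_PRIMERS),
]

#: haplotype-count weights reconstructed from the published pool percentages
POOLED_PRIMERS_F_WEIGHTS = (5, 2, 2, 1, 1)  # fa 45.5% fb 18.2% fc 18.2% fd 9.1% fe 9.1%
POOLED_PRIMERS_R_WEIGHTS = (5, 2, 1, 1, 1, 1, 1)  # ra 41.7% rb 16.7% rc..rg 8.3%
POOLED_PCRS_FRACTIONS = (0.5, 1 / 6, 1 / 6, 1 / 6)  # f1-r1 50%, f2-r1 / f1-r2 / f1-r3 16.6%

ALL_PRIMERS = [
    CONVENTIONAL_F,
    CONVENTIONAL_R,
    POOLED_PCRS_F1,
    POOLED_PCRS_F2,
    POOLED_PCRS_R1,
    POOLED_PCRS_R2,
    POOLED_PCRS_R3,
    *POOLED_PRIMERS_F,
    *POOLED_PRIMERS_R,
]


def forward_pool() -> PrimerPool:
    return PrimerPool(tuple(POOLED_PRIMERS_F), POOLED_PRIMERS_F_WEIGHTS)


def reverse_pool() -> PrimerPool:
    return PrimerPool(tuple(POOLED_PRIMERS_R), POOLED_PRIMERS_R_WEIGHTS)


def conventional_assay() -> list[PCRAssay]:
    """Single PCR with the highly degenerate pair."""
    return [
        PCRAssay(
            "f-r",
            ((CONVENTIONAL_F, 1.0),),
            ((CONVENTIONAL_R, 1.0),),
            fraction=1.0,
        )
    ]


def pooled_pcrs_assay() -> list[PCRAssay]:
    """Four independent PCRs pooled for sequencing by expected locus counts."""
    pairs = [
        ("f1-r1", POOLED_PCRS_F1, POOLED_PCRS_R1),
        ("f2-r1", POOLED_PCRS_F2, POOLED_PCRS_R1),
        ("f1-r2", POOLED_PCRS_F1, POOLED_PCRS_R2),
        ("f1-r3", POOLED_PCRS_F1, POOLED_PCRS_R3),
    ]
    return [
        PCRAssay(name, ((f, 1.0),), ((r, 1.0),), fraction=frac)
        for (name, f, r), frac in zip(pairs, POOLED_PCRS_FRACTIONS)
    ]


def pooled_primers_assay() -> list[PCRAssay]:
    """Single PCR mixing all non-degenerate primers at pool proportions."""
    fpool, rpool = forward_pool(), reverse_pool()
    return [
        PCRAssay(
            "pooled",
            tuple(zip(fpool.members, fpool.proportions())),
            tuple(zip(rpool.members, rpool.proportions())),
            fraction=1.0,
        )
    ]


def assay_for(strategy: str) -> list[PCRAssay]:
    if strategy == CONVENTIONAL:
        return conventional_assay()
    if strategy == POOLED_PCRS:
        return pooled_pcrs_assay()
    if strategy == POOLED_PRIMERS:
        return pooled_primers_assay()
    raise ValueError(f"unknown strategy {strategy!r}")
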