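"""Built-in input tables for the CYP1A2/phenacetin relaxation study.

These are the measured inputs of the four-enzyme study — per-proton T1
pairs in the ferric and ferrous-CO states, enzyme and substrate
concentrations, spectral binding constants, phenacetin-bound spin-state
fractions, and the dipolar correlation time — from which the distance
table is computed at run time.  Distances are never stored here.

Proton labels refer to phenacetin: the aromatic 2,6 and 3,5 ring
protons, the -OCH2- methylene of the ethoxy group (the site of
metabolism, whose hydrogen is abstracted during O-deethylation), the
-COCH3 acetyl methyl, and the -CH3 ethoxy methyl.

Note on the L382V enzyme concentration: the source study's footnote
prints 0.007 uM, which is internally inconsistent with its own distance
table; every other enzyme's concentration equals 1e-3 times its Ks, and
only 0.0007 uM (= 1e-3 * 0.7 uM) reproduces the four printed L382V
distances.  The corrected value ships as the default, with the printed
one kept alongside for transparency.
"""

from __future__ import annotations

from .pipeline import EnzymeStudy, StudyConfig
from .relaxation import RelaxationPair

__all__ = [
    "TAU_C_S",
    "SITE_OF_METABOLISM",
    "L382V_PRINTED_P450_UM",
    "cyp1a2_phenacetin_study",
]

#: Dipolar correlation time for CYP1A2 (seconds).
TAU_C_S = 3.38e-10

#: The proton abstracted during phenacetin O-deethylation.
SITE_OF_METABOLISM = "-OCH2-"

#: The footnote-printed (inconsistent) L382V enzyme concentration, µM.
L382V_PRINTED_P450_UM = 0.007

# label: (p450_uM, substrate_uM, ks_uM, f_high)
_CONDITIONS = {
    "CYP1A2 WT": (0.017, 171.0, 17.1, 0.27),
    "CYP1A2 L382V": (0.0007, 7.0, 0.7, 0.21),
    "CYP1A2 N312L": (0.011, 102.0, 10.2, 0.14),
    "CYP1A2 L382V/N312L": (0.004, 35.0, 3.5, 0.17),
}

# label -> proton -> (t1_ferric, se_ferric, t1_ferrous_co, se_ferrous_co), s
_T1_PAIRS = {
    "CYP1A2 WT": {
        "2,6": (2.22, 0.11, 2.78, 0.05),
        "3,5": (2.02, 0.04, 2.50, 0.01),
        "-OCH2-": (1.54, 0.15, 1.85, 0.18),
        "-COCH3": (1.53, 0.07, 1.62, 0.06),
        "-CH3": (1.33, 0.07, 1.53, 0.06),
    },
    "CYP1A2 L382V": {
        "2,6": (2.28, 0.11, 3.06, 0.04),
        "3,5": (2.39, 0.22, 3.21, 0.08),
        "-OCH2-": (2.43, 0.18, 4.10, 0.07),
        "-COCH3": (1.64, 0.13, 1.87, 0.11),
        "-CH3": (2.03, 0.13, 2.82, 0.11),
    },
    "CYP1A2 N312L": {
        "2,6": (2.32, 0.10, 2.45, 0.10),
        "3,5": (1.94, 0.09, 2.04, 0.10),
        "-OCH2-": (1.62, 0.04, 1.69, 0.04),
        "-COCH3": (1.54, 0.12, 1.60, 0.11),
        "-CH3": (1.87, 0.12, 1.97, 0.07),
    },
    "CYP1A2 L382V/N312L": {
        "2,6": (2.43, 0.07, 3.00, 0.06),
        "3,5": (2.95, 0.09, 3.70, 0.11),
        "-OCH2-": (1.98, 0.12, 2.90, 0.09),
        "-COCH3": (2.12, 0.14, 2.59, 0.12),
        "-CH3": (2.23, 0.09, 2.61, 0.11),
    },
}


def cyp1a2_phenacetin_study() -> StudyConfig:
    """Assemble the four-enzyme CYP1A2/phenacetin study configuration."""
    studies = []
    for label, (p450, sub, ks, f_high) in _CONDITIONS.items():
        pairs = [
            RelaxationPair(proton_label=lab, t1_ferric=t1f, se_ferric=sef,
                           t1_ferrous_co=t1co, se_ferrous_co=seco)
            for lab, (t1f, sef, t1co, seco) in _T1_PAIRS[label].items()
        ]
        studies.append(
            EnzymeStudy(
                enzyme_label=label,
                p450_conc=p450,
                substrate_conc=sub,
                ks=ks,
                f_high=f_high,
                f_low=1.0 - f_high,
                tau_c=TAU_C_S,
                relaxation_pairs=tuple(pairs),
            )
        )
    return StudyConfig(enzymes=tuple(studies))
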