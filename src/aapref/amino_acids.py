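"""Amino-acid constants shared across the package.

Concentrations are in micromolar (uM) throughout. Cysteine is essential for
the modelled organism (its biosynthesis pathway is incomplete) and is held
fixed at the reference concentration; the remaining 19 amino acids are the
design variables.
"""

from __future__ import annotations

#: 20 proteinogenic amino acids, alphabetical by three-letter code.
AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

CYSTEINE = "Cys"

#: The 19 optimization variables (cysteine excluded), alphabetical.
VARIABLE_AMINO_ACIDS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if aa != CYSTEINE
)

#: Discrete concentration levels used in the experimental designs (uM).
LEVELS_UM: tuple[float, ...] = (0.0, 4.0, 40.0, 400.0)

#: Reference ("ALL") per-amino-acid concentration (uM).
REFERENCE_CONCENTRATION_UM = 400.0

#: Total amino-acid content of the ALL medium: 20 x 400 uM.
AA_ALL_TOTAL_UM = REFERENCE_CONCENTRATION_UM * len(AMINO_ACIDS)

CARBON_SOURCES = ("glucose", "lactose")
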