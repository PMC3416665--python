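"""Residue alphabets and fixed column orderings shared across the package.

All composition tables use the alphabetical one-letter ordering
:data:`RESIDUES`; every module that emits a 20-column matrix documents its
columns as this order.
"""

# The 20 standard amino acids, alphabetical by one-letter code.
RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

RESIDUE_SET = frozenset(RESIDUES)

# Ambiguity / non-standard codes permitted on input but excluded from every
# composition denominator: Asx, Glx, unknown, selenocysteine.
AMBIGUOUS: str = "BZXU"

#: Three-letter names, used for human-readable outputs (Table-style reports).
THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}

# The eight residues whose codons carry no G+C bias; the remaining twelve are
# pooled into an "other" column in the GC-unbiased usage reduction.
UNBIASED_RESIDUES: str = "VSTHQDEC"

# Residues encoded by GC-rich codons (enriched in high-GC genomes) and by
# AU-rich codons (enriched in low-GC genomes); used by monotonicity checks
# on GC-driven synthetic proteomes.
GC_RICH_RESIDUES: str = "PARG"
AT_RICH_RESIDUES: str = "FYKNI"

# The 25-letter COG functional-category alphabet.
COG_CATEGORIES: str = "JAKLBDYVTMNZWUOCGEFHIPQRS"
COG_CATEGORY_SET = frozenset(COG_CATEGORIES)
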