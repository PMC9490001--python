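"""Reference constants for random-coil amide exchange rates.

Standard poly-DL-alanine reference formalism (low-salt D2O, 20 C reference):
the intrinsic rate of an internal amide is

    k_int = k_A * A * [D+]  +  k_B * B * [OD-]  +  k_W * B,

where A and B collect the multiplicative (log10-additive) nearest-neighbour
side-chain corrections of the amide's own residue ("self" columns) and of the
preceding residue ("prev" columns), [OD-] follows from pD via the D2O
autoionisation constant, and each catalytic term carries its own Arrhenius
activation energy for temperature scaling.

Rates below are per minute at the 293 K reference; ``intrinsic_rates``
converts to s^-1.  Side-chain entries use the ionisation forms appropriate
near neutral pD (Asp-/Glu- carboxylates, neutral His, reduced Cys); terminal
corrections are the standard free-terminus values (protonated N-terminal
ammonium; COOH-form C-terminus).
"""

# log10 reference rates for poly-DL-alanine (min^-1; acid/base terms are
# second order in catalyst concentration)
ACID_REF_LOG10 = 1.62
BASE_REF_LOG10 = 10.05
WATER_REF_LOG10 = -1.5

PKD = 15.05  # D2O autoionisation, molar scale
T_REF = 293.0  # K

# activation energies (kcal/mol) for the three catalytic terms
EA_ACID = 14.0
EA_BASE = 17.0
EA_WATER = 19.0

# per-residue log10 corrections: (acid_self, acid_prev, base_self, base_prev)
# "self" applies to the amide of the residue itself, "prev" when the residue
# precedes the exchanging amide
SIDE_CHAIN_LOG10 = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, 0.10, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "E": (-0.90, 0.31, -0.11, -0.15),
    "H": (0.00, 0.00, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
    "X": (0.00, 0.00, 0.00, 0.00),
}

# (acid, base) log10 corrections for the chain termini
NTERM_LOG10 = (-1.32, 1.62)
CTERM_LOG10 = (0.96, -1.80)
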