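"""Versioned hydrophobicity coefficient table for the SSRCalc-style index.

Residue retention coefficients for a 100 A pore C18 column with TFA ion
pairing, as published for the sequence-specific retention calculator
(Krokhin et al. 2004, Mol Cell Proteomics 3:908) and distributed with
common proteomics toolkits. ``RC`` is the bulk residue coefficient; ``RC_NT``
is the coefficient applied (attenuated) to the first three residues, which
sit near the charged N-terminus and contribute less to retention. The
N-terminal column is an approximation documented in the methods note; the
table is versioned so an alternative calibrated set can be swapped in.
"""

SSRCALC_VERSION = "100A-tfa-v1"

#: Bulk residue retention coefficients (dimensionless index units).
RC: dict[str, float] = {
    "A": 1.11,
    "C": 0.04,
    "D": -0.22,
    "E": 1.08,
    "F": 11.34,
    "G": -0.35,
    "H": -3.04,
    "I": 7.86,
    "K": -3.53,
    "L": 9.44,
    "M": 6.57,
    "N": -1.44,
    "P": 1.62,
    "Q": -0.53,
    "R": -2.58,
    "S": -0.33,
    "T": 0.48,
    "V": 4.86,
    "W": 13.12,
    "Y": 5.40,
}

#: N-terminal coefficients: hydrophobic residues near the charged terminus
#: retain less, hydrophilic ones slightly more, than in the bulk.
RC_NT: dict[str, float] = {
    "A": -1.5,
    "C": 4.0,
    "D": 9.0,
    "E": 7.0,
    "F": -7.0,
    "G": 5.0,
    "H": 4.0,
    "I": -8.0,
    "K": 4.6,
    "L": -9.0,
    "M": -5.5,
    "N": 5.0,
    "P": 4.0,
    "Q": 1.0,
    "R": 8.0,
    "S": 5.0,
    "T": 5.0,
    "V": -5.5,
    "W": -4.0,
    "Y": -3.0,
}

#: Attenuation weights for the first three N-terminal positions.
NT_WEIGHTS = (0.42, 0.22, 0.05)
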