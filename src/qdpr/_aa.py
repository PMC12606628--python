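"""Amino-acid alphabet and the built-in physicochemical descriptor table.

The descriptor table collects 19 widely used per-residue scales (hydropathy,
steric volume, charge, secondary-structure propensities, hydrogen-bonding
capacity, ...). Channels are standardized to zero mean and unit variance over
the 20-letter alphabet before use in sequence encodings, so only the relative
ordering of amino acids within each scale matters. User-supplied tables with
the same layout may be used instead.
"""

from __future__ import annotations

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

# fmt: off
_DESCRIPTORS: dict[str, dict[str, float]] = {
    "hydropathy": {  # Kyte-Doolittle
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
        "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
        "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
        "W": -0.9, "Y": -1.3},
    "volume": {  # residue volume, A^3
        "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
        "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
        "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
        "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6},
    "residue_mass": {
        "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
        "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
        "M": 131.20, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
        "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18},
    "isoelectric_point": {
        "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
        "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
        "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96,
        "W": 5.89, "Y": 5.66},
    "net_charge_ph7": {
        "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0,
        "H": 0.1, "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 0.0, "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0,
        "W": 0.0, "Y": 0.0},
    "polarity": {  # Grantham
        "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
        "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
        "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
        "W": 5.4, "Y": 6.2},
    "helix_penalty": {  # helix propensity, kcal/mol relative to Ala
        "A": 0.00, "C": 0.68, "D": 0.69, "E": 0.40, "F": 0.54, "G": 1.00,
        "H": 0.61, "I": 0.41, "K": 0.26, "L": 0.21, "M": 0.24, "N": 0.65,
        "P": 3.16, "Q": 0.39, "R": 0.21, "S": 0.50, "T": 0.66, "V": 0.61,
        "W": 0.49, "Y": 0.53},
    "sheet_propensity": {  # Chou-Fasman P(b)
        "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
        "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30, "M": 1.05, "N": 0.89,
        "P": 0.55, "Q": 1.10, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.70,
        "W": 1.37, "Y": 1.47},
    "turn_propensity": {  # Chou-Fasman P(t)
        "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60, "G": 1.56,
        "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59, "M": 0.60, "N": 1.56,
        "P": 1.52, "Q": 0.98, "R": 0.95, "S": 1.43, "T": 0.96, "V": 0.50,
        "W": 0.96, "Y": 1.14},
    "flexibility": {
        "A": 0.36, "C": 0.35, "D": 0.51, "E": 0.50, "F": 0.31, "G": 0.54,
        "H": 0.32, "I": 0.46, "K": 0.47, "L": 0.37, "M": 0.30, "N": 0.46,
        "P": 0.51, "Q": 0.49, "R": 0.53, "S": 0.51, "T": 0.44, "V": 0.39,
        "W": 0.31, "Y": 0.42},
    "max_asa": {  # theoretical maximum solvent accessibility, A^2
        "A": 129.0, "C": 167.0, "D": 193.0, "E": 223.0, "F": 240.0,
        "G": 104.0, "H": 224.0, "I": 197.0, "K": 236.0, "L": 201.0,
        "M": 224.0, "N": 195.0, "P": 159.0, "Q": 225.0, "R": 274.0,
        "S": 155.0, "T": 172.0, "V": 174.0, "W": 285.0, "Y": 263.0},
    "aromaticity": {
        "A": 0.0, "C": 0.0, "D": 0.0, "E": 0.0, "F": 1.0, "G": 0.0,
        "H": 0.5, "I": 0.0, "K": 0.0, "L": 0.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 0.0, "R": 0.0, "S": 0.0, "T": 0.0, "V": 0.0,
        "W": 1.0, "Y": 1.0},
    "aliphaticity": {
        "A": 1.0, "C": 0.0, "D": 0.0, "E": 0.0, "F": 0.0, "G": 0.0,
        "H": 0.0, "I": 1.0, "K": 0.0, "L": 1.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 0.0, "R": 0.0, "S": 0.0, "T": 0.0, "V": 1.0,
        "W": 0.0, "Y": 0.0},
    "hbond_donors": {  # side-chain donor groups
        "A": 0.0, "C": 0.0, "D": 0.0, "E": 0.0, "F": 0.0, "G": 0.0,
        "H": 1.0, "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 1.0,
        "P": 0.0, "Q": 1.0, "R": 2.0, "S": 1.0, "T": 1.0, "V": 0.0,
        "W": 1.0, "Y": 1.0},
    "hbond_acceptors": {  # side-chain acceptor groups
        "A": 0.0, "C": 0.0, "D": 2.0, "E": 2.0, "F": 0.0, "G": 0.0,
        "H": 1.0, "I": 0.0, "K": 0.0, "L": 0.0, "M": 0.0, "N": 1.0,
        "P": 0.0, "Q": 1.0, "R": 0.0, "S": 1.0, "T": 1.0, "V": 0.0,
        "W": 0.0, "Y": 1.0},
    "hydrophobicity": {  # Eisenberg consensus
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26},
    "bulkiness": {  # Zimmerman
        "A": 11.50, "C": 13.46, "D": 11.68, "E": 13.57, "F": 19.80,
        "G": 3.40, "H": 13.69, "I": 21.40, "K": 15.71, "L": 21.40,
        "M": 16.25, "N": 12.82, "P": 17.43, "Q": 14.45, "R": 14.28,
        "S": 9.47, "T": 15.77, "V": 21.57, "W": 21.67, "Y": 18.03},
    "refractivity": {
        "A": 4.34, "C": 35.77, "D": 12.00, "E": 17.26, "F": 29.40,
        "G": 0.00, "H": 21.81, "I": 19.06, "K": 21.29, "L": 18.78,
        "M": 21.64, "N": 13.28, "P": 10.93, "Q": 17.56, "R": 26.66,
        "S": 6.35, "T": 11.01, "V": 13.92, "W": 42.53, "Y": 31.53},
    "sidechain_heavy_atoms": {
        "A": 1.0, "C": 2.0, "D": 4.0, "E": 5.0, "F": 7.0, "G": 0.0,
        "H": 6.0, "I": 4.0, "K": 5.0, "L": 4.0, "M": 4.0, "N": 4.0,
        "P": 3.0, "Q": 5.0, "R": 7.0, "S": 2.0, "T": 3.0, "V": 3.0,
        "W": 10.0, "Y": 8.0},
}
# fmt: on

DESCRIPTOR_NAMES: tuple[str, ...] = tuple(_DESCRIPTORS)


def descriptor_table(standardize: bool = True) -> np.ndarray:
    """Return the (20, n_descriptors) table in alphabet order.

    With ``standardize=True`` each column is shifted/scaled to zero mean and
    unit (population) variance over the 20 amino acids.
    """
    table = np.array(
        [[_DESCRIPTORS[name][aa] for name in DESCRIPTOR_NAMES] for aa in AA_ALPHABET],
        dtype=float,
    )
    if standardize:
        table = (table - table.mean(axis=0)) / table.std(axis=0)
    return table
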