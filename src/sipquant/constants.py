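"""Physical constants and residue composition tables.

Both tables are shipped as plain-text TSV files under ``sipquant/data`` and
loaded once at import time, so that the exact values the package computes
with are inspectable and pinned by tests.
"""

from __future__ import annotations

from importlib import resources

__all__ = [
    "RESIDUE_COMPOSITIONS",
    "CONSTANTS",
    "MASS_PROTON",
    "DELTA_13C",
    "NATURAL_13C",
    "ELEMENT_MASSES",
    "NATURAL_CHANNELS",
]


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("sipquant.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _load_residues() -> dict[str, dict[str, int]]:
    rows = _read_tsv("residue_compositions.tsv")
    header = rows[0][1:]
    table = {}
    for row in rows[1:]:
        table[row[0]] = {el: int(v) for el, v in zip(header, row[1:])}
    return table


def _load_constants() -> dict[str, float]:
    rows = _read_tsv("isotope_constants.tsv")
    assert rows[0] == ["constant", "value"]
    return {name: float(value) for name, value in rows[1:]}


#: residue one-letter code -> {"C": n, "H": n, "N": n, "O": n, "S": n}
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = _load_residues()

CONSTANTS: dict[str, float] = _load_constants()

MASS_PROTON: float = CONSTANTS["mass_proton"]
#: mass difference between 13C and 12C, Da
DELTA_13C: float = CONSTANTS["delta_13C"]
#: natural 13C atom fraction
NATURAL_13C: float = CONSTANTS["abundance_13C"]

#: monoisotopic (lightest-isotope) atomic masses, Da
ELEMENT_MASSES: dict[str, float] = {
    "C": CONSTANTS["mass_C12"],
    "H": CONSTANTS["mass_H1"],
    "N": CONSTANTS["mass_N14"],
    "O": CONSTANTS["mass_O16"],
    "S": CONSTANTS["mass_S32"],
}

#: per-atom probability of occupying the +0 / +1 / +2 heavy-mass-unit channel
#: at natural abundance, for the non-carbon elements.
NATURAL_CHANNELS: dict[str, tuple[float, ...]] = {
    "H": (1.0 - CONSTANTS["abundance_2H"], CONSTANTS["abundance_2H"]),
    "N": (1.0 - CONSTANTS["abundance_15N"], CONSTANTS["abundance_15N"]),
    "O": (
        1.0 - CONSTANTS["abundance_17O"] - CONSTANTS["abundance_18O"],
        CONSTANTS["abundance_17O"],
        CONSTANTS["abundance_18O"],
    ),
    "S": (
        1.0 - CONSTANTS["abundance_33S"] - CONSTANTS["abundance_34S"],
        CONSTANTS["abundance_33S"],
        CONSTANTS["abundance_34S"],
    ),
}
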