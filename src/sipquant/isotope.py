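"""Peptide elemental composition, monoisotopic mass, and isotopologue
distributions under arbitrary ¹³C enrichment.

The isotopologue model indexes peptide isotopologues by their integer
heavy-mass-unit offset ``k`` from the monoisotopic peak. Carbon contributes a
Binomial(n_C, ria) number of heavy units, where ``ria`` (relative isotope
abundance) is the per-carbon probability of being ¹³C; the other elements
contribute their natural-abundance +1/+2 channels (²H, ¹⁵N; ¹⁷O/¹⁸O;
³³S/³⁴S). The total offset distribution is the convolution of the per-element
distributions. Fine mass differences between heavy-isotope channels (e.g.
¹³C vs ¹⁵N substitution) are deliberately ignored: the model operates at the
resolution of the MS1 envelope, where peaks one heavy unit apart are the
objects of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import (
    DELTA_13C,
    ELEMENT_MASSES,
    MASS_PROTON,
    NATURAL_13C,
    NATURAL_CHANNELS,
    RESIDUE_COMPOSITIONS,
)

__all__ = [
    "ElementalComposition",
    "PeptideIon",
    "IsotopePattern",
    "composition_of",
    "monoisotopic_mass",
    "monoisotopic_mz",
    "heavy_isotopologue_mz",
    "isotope_pattern",
]

# composition deltas of supported residue-level modifications
_MODIFICATIONS: dict[str, dict[str, int]] = {
    # iodoacetamide alkylation of cysteine, fixed in the reference workflow
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    # methionine oxidation, +1 oxygen
    "oxidation": {"O": 1},
}

_MOD_TARGETS = {"carbamidomethyl": "C", "oxidation": "M"}


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a neutral molecule (C, H, N, O, S)."""

    n_C: int
    n_H: int
    n_N: int
    n_O: int
    n_S: int = 0

    def __post_init__(self) -> None:
        for name in ("n_C", "n_H", "n_N", "n_O", "n_S"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return {
            "C": self.n_C,
            "H": self.n_H,
            "N": self.n_N,
            "O": self.n_O,
            "S": self.n_S,
        }

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da (all atoms lightest isotope)."""
        return sum(n * ELEMENT_MASSES[el] for el, n in self.as_dict().items())


@dataclass(frozen=True)
class PeptideIon:
    """A peptide sequence with charge state and fixed modifications.

    ``fixed_modifications`` names residue-level adjustments applied to every
    matching residue; supported: ``"carbamidomethyl"`` (C),
    ``"oxidation"`` (M).
    """

    sequence: str
    charge: int = 1
    fixed_modifications: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        for mod in self.fixed_modifications:
            if mod not in _MODIFICATIONS:
                raise ValueError(f"unsupported modification: {mod!r}")


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue abundances indexed by heavy-mass-unit offset ``k``.

    ``abundances[i]`` is the probability of offset ``k[i]``; abundances sum
    to 1 before pruning and keep their absolute scale afterwards unless
    renormalization was requested.
    """

    k: np.ndarray
    abundances: np.ndarray
    ria_c: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.k) <= 0):
            raise ValueError("k offsets must be strictly increasing")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def modal_k(self) -> int:
        return int(self.k[int(np.argmax(self.abundances))])

    @property
    def mean_k(self) -> float:
        return float(np.sum(self.k * self.abundances) / np.sum(self.abundances))

    def as_vector(self, k_max: int | None = None) -> np.ndarray:
        """Dense abundance vector over k = 0..k_max (default: max stored k)."""
        if k_max is None:
            k_max = int(self.k[-1])
        out = np.zeros(k_max + 1)
        sel = self.k <= k_max
        out[self.k[sel]] = self.abundances[sel]
        return out


def composition_of(ion: PeptideIon) -> ElementalComposition:
    """Summed residue composition of a peptide ion plus one water.

    Fixed modifications are applied per matching residue. Raises
    ``ValueError`` naming the first unknown residue letter.
    """
    totals = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}  # start from H2O
    for ch in ion.sequence:
        try:
            res = RESIDUE_COMPOSITIONS[ch]
        except KeyError:
            raise ValueError(
                f"unknown residue {ch!r} in sequence {ion.sequence!r}"
            ) from None
        for el, n in res.items():
            totals[el] += n
    for mod in ion.fixed_modifications:
        n_targets = ion.sequence.count(_MOD_TARGETS[mod])
        for el, n in _MODIFICATIONS[mod].items():
            totals[el] += n * n_targets
    return ElementalComposition(
        n_C=totals["C"], n_H=totals["H"], n_N=totals["N"],
        n_O=totals["O"], n_S=totals["S"],
    )


def monoisotopic_mass(ion: PeptideIon) -> float:
    """Neutral monoisotopic mass of the peptide, Da."""
    return composition_of(ion).monoisotopic_mass


def monoisotopic_mz(ion: PeptideIon) -> float:
    """Monoisotopic m/z of the protonated ion: (M + z·m_p) / z."""
    return (monoisotopic_mass(ion) + ion.charge * MASS_PROTON) / ion.charge


def heavy_isotopologue_mz(ion: PeptideIon, k: int) -> float:
    """m/z of the isotopologue ``k`` heavy-mass units above monoisotopic.

    All heavy units are placed on the ¹³C mass ladder
    (Δm = 1.0033548 Da per unit).
    """
    if k < 0:
        raise ValueError("isotopologue offset k must be >= 0")
    return monoisotopic_mz(ion) + k * DELTA_13C / ion.charge


def _natural_element_pattern(n_atoms: int, channels: tuple[float, ...]) -> np.ndarray:
    """Offset distribution of ``n_atoms`` i.i.d. atoms with per-atom channel
    probabilities ``channels`` (index = heavy-mass-unit contribution)."""
    out = np.array([1.0])
    base = np.asarray(channels, dtype=float)
    # exponentiation by squaring under convolution
    power = base
    n = n_atoms
    while n > 0:
        if n & 1:
            out = np.convolve(out, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return out


def isotope_pattern(
    comp: ElementalComposition,
    ria_c: float = NATURAL_13C,
    prune: float = 1e-6,
    renormalize: bool = False,
) -> IsotopePattern:
    """Isotopologue distribution of ``comp`` at per-carbon ¹³C fraction
    ``ria_c``.

    Carbon contributes Binomial(n_C, ria_c) heavy units; H, N, O, S
    contribute their natural +1/+2 channels. Entries with abundance below
    ``prune`` are removed after the full distribution is formed; by default
    the surviving entries keep their absolute scale (they then sum to
    slightly less than 1), so goodness-of-fit statistics see the true tail
    mass. Pass ``renormalize=True`` to rescale the survivors to sum to 1.
    """
    if not 0.0 <= ria_c <= 1.0:
        raise ValueError("ria_c must lie in [0, 1]")
    if not 0.0 <= prune < 0.01:
        raise ValueError("prune must lie in [0, 0.01)")
    dist = stats.binom.pmf(np.arange(comp.n_C + 1), comp.n_C, ria_c)
    for el in ("H", "N", "O", "S"):
        n = comp.as_dict()[el]
        if n:
            dist = np.convolve(dist, _natural_element_pattern(n, NATURAL_CHANNELS[el]))
    k = np.arange(dist.size)
    keep = dist >= prune
    if not np.any(keep):  # degenerate; keep the mode
        keep[np.argmax(dist)] = True
    k, dist = k[keep], dist[keep]
    if renormalize:
        dist = dist / dist.sum()
    return IsotopePattern(k=k, abundances=dist, ria_c=float(ria_c))
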