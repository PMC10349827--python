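"""Elemental compositions, exact ion masses and isotope patterns.

Heavy metals deposited with an NEDC (N-naphthylethylenediamine
dihydrochloride) matrix ionize in negative mode as chloride adduct anions
([MCl2]-, [MCl3]-); organic pollutants ionize in positive mode as
protonated molecules and alkali adducts.  Both are screened by exact mass,
so every downstream stage rests on the arithmetic in this module:

* exact ion m/z from an elemental composition, using the MOST ABUNDANT
  isotope of each element and correcting for electron mass;
* theoretical isotope patterns by exhaustive multinomial enumeration of
  isotopologues, with peak merging and low-abundance truncation;
* an open isotope-fit statistic ("sigma score") with the convention that
  0 is a perfect fit and scores <= 30 indicate a good isotopic match.

Isotope masses and abundances are pinned to a vendored NIST-derived
constants file (``data/isotopes.tsv``) so results are bit-stable.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

ELECTRON_MASS_DA = 0.00054858
"""Electron rest mass in Da, subtracted once per positive charge."""

UNMATCHED = float("inf")
"""Sentinel sigma score when a required isotopologue has no measured match."""

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ChemError(ValueError):
    """Raised for malformed formulas or missing isotope data."""


# ---------------------------------------------------------------------------
# Isotope table
# ---------------------------------------------------------------------------

class ElementIsotopeTable:
    """Mapping element symbol -> [(isotope mass Da, abundance fraction)].

    Masses are strictly increasing within an element and abundances sum to
    one within 1e-6 (validated on load).
    """

    REQUIRED = frozenset(
        "C H N O S P F Cl Na K Mg Mn Fe Ni Cu Zn Cd Pb".split()
    )

    def __init__(self, isotopes: Mapping[str, Sequence[tuple[float, float]]]):
        self._table = {el: tuple(iso) for el, iso in isotopes.items()}
        self._validate()

    def _validate(self) -> None:
        missing = self.REQUIRED - set(self._table)
        if missing:
            raise ChemError(f"isotope table lacks required elements: {sorted(missing)}")
        for el, iso in self._table.items():
            masses = [m for m, _ in iso]
            if masses != sorted(masses) or len(set(masses)) != len(masses):
                raise ChemError(f"isotope masses for {el} not strictly increasing")
            total = sum(a for _, a in iso)
            if abs(total - 1.0) > 1e-6:
                raise ChemError(f"abundances for {el} sum to {total}, not 1")

    def __contains__(self, element: str) -> bool:
        return element in self._table

    def __getitem__(self, element: str) -> tuple[tuple[float, float], ...]:
        try:
            return self._table[element]
        except KeyError:
            raise ChemError(f"element {element!r} missing from isotope table") from None

    def elements(self) -> list[str]:
        return sorted(self._table)

    def most_abundant_mass(self, element: str) -> float:
        """Mass of the most abundant isotope (not necessarily the lightest:
        e.g. cadmium's principal isotope is 114Cd)."""
        return max(self[element], key=lambda t: t[1])[0]

    def monoisotopic_mass(self, element: str) -> float:
        return self.most_abundant_mass(element)

    @classmethod
    def from_file(cls, path) -> "ElementIsotopeTable":
        table: dict[str, list[tuple[float, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                el, mass, ab = line.split("\t")
                table.setdefault(el, []).append((float(mass), float(ab)))
        return cls(table)

    @classmethod
    def default(cls) -> "ElementIsotopeTable":
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            ref = resources.files("biosolid_msi.data") / "isotopes.tsv"
            with resources.as_file(ref) as path:
                _DEFAULT_TABLE = cls.from_file(path)
        return _DEFAULT_TABLE


_DEFAULT_TABLE: ElementIsotopeTable | None = None


# ---------------------------------------------------------------------------
# Formulas and ions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Formula:
    """Elemental composition as an element -> count map (counts >= 1)."""

    counts: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "counts", dict(self.counts))
        for el, n in self.counts.items():
            if not isinstance(n, int) or n < 1:
                raise ChemError(f"count for {el} must be a positive integer, got {n}")

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def to_string(self) -> str:
        """Canonical Hill notation: C, H first (when carbon present), then
        the remaining elements alphabetically."""
        els = set(self.counts)
        if "C" in els:
            order = ["C"] + (["H"] if "H" in els else []) + sorted(els - {"C", "H"})
        else:
            order = sorted(els)
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] > 1 else ''}" for el in order
        )

    def monoisotopic_mass(self, table: ElementIsotopeTable | None = None) -> float:
        """Neutral mass using the most abundant isotope of each element."""
        table = table or ElementIsotopeTable.default()
        return sum(table.most_abundant_mass(el) * n for el, n in self.counts.items())


def parse_formula(text: str, table: ElementIsotopeTable | None = None) -> Formula:
    """Parse a Hill-style element-count string such as ``"C25H28N6O"``.

    No parentheses, isotope labels or charge signs are accepted; counts of
    zero are rejected.
    """
    table = table or ElementIsotopeTable.default()
    if not text or not text.strip():
        raise ChemError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ChemError(f"cannot parse formula {text!r} at position {pos}")
        el, num = match.group(1), match.group(2)
        if el not in table:
            raise ChemError(f"unknown element symbol {el!r} in {text!r}")
        n = int(num) if num else 1
        if n < 1:
            raise ChemError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = match.end()
    if pos != len(text):
        raise ChemError(f"cannot parse formula {text!r} at position {pos}")
    return Formula(counts)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species: composition plus a signed integer charge."""

    formula: Formula
    charge: int
    label: str = ""

    def __post_init__(self):
        if self.charge == 0:
            raise ChemError("ion charge must be nonzero")


def ion_mz(species: IonSpecies, table: ElementIsotopeTable | None = None) -> float:
    """Monoisotopic m/z of an ion.

    Uses the most abundant isotope of every element and subtracts ``z``
    electron masses (so anions gain electron mass), divided by ``|z|``.
    Full float precision is returned; rounding or truncation for display is
    left to the caller.
    """
    table = table or ElementIsotopeTable.default()
    mass = species.formula.monoisotopic_mass(table)
    return (mass - species.charge * ELECTRON_MASS_DA) / abs(species.charge)


def truncate_mz(mz: float, decimals: int = 4) -> float:
    """Truncate (not round) an m/z to the given number of decimals, the
    convention used for printed calibration masses."""
    factor = 10.0 ** decimals
    return math.floor(mz * factor) / factor


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

@dataclass
class IsotopePattern:
    """Centroided theoretical isotope pattern of one ion.

    ``peaks`` holds (m/z, abundance fraction) sorted by m/z.  Abundances
    are fractions of the full (pre-truncation) pattern; after dropping
    entries below ``min_abundance`` they are deliberately NOT renormalized,
    and ``retained_fraction`` records how much abundance survives.
    """

    peaks: list[tuple[float, float]]
    merge_tol: float
    min_abundance: float
    retained_fraction: float = 1.0
    label: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> list[float]:
        return [p[0] for p in self.peaks]

    @property
    def abundances(self) -> list[float]:
        return [p[1] for p in self.peaks]

    def base_peak(self) -> tuple[float, float]:
        return max(self.peaks, key=lambda p: p[1])


def _element_distribution(
    isotopes: Sequence[tuple[float, float]], n: int, prune: float
) -> list[tuple[float, float]]:
    """(mass, probability) of n atoms of one element, aggregated over
    isotope count vectors with multinomial weights."""
    out: list[tuple[float, float]] = []
    k = len(isotopes)
    # compositions of n into k parts
    for split in itertools.combinations_with_replacement(range(k), n):
        counts = [0] * k
        for idx in split:
            counts[idx] += 1
        prob = math.factorial(n)
        mass = 0.0
        for c, (m, a) in zip(counts, isotopes):
            prob = prob / math.factorial(c) * a ** c
            mass += c * m
        if prob >= prune:
            out.append((mass, prob))
    return out


def _merge_peaks(
    peaks: list[tuple[float, float]], merge_tol: float
) -> list[tuple[float, float]]:
    """Greedy abundance-weighted centroid merge of peaks closer than
    ``merge_tol`` on a sorted list."""
    merged: list[tuple[float, float]] = []
    for mz, ab in sorted(peaks):
        if merged and mz - merged[-1][0] < merge_tol:
            pmz, pab = merged[-1]
            tot = pab + ab
            merged[-1] = ((pmz * pab + mz * ab) / tot, tot)
        else:
            merged.append((mz, ab))
    return merged


def theoretical_pattern(
    species: IonSpecies,
    table: ElementIsotopeTable | None = None,
    min_abundance: float = 0.01,
    merge_tol: float = 0.005,
    _prune: float = 1e-12,
) -> IsotopePattern:
    """Exhaustive isotopologue enumeration for an ion.

    Per-element multinomial distributions are convolved across elements
    (terms below ``_prune`` dropped to bound the combinatorics), isotopologues
    closer than ``merge_tol`` Da are merged to an abundance-weighted
    centroid, and entries below ``min_abundance`` are discarded without
    renormalization.
    """
    table = table or ElementIsotopeTable.default()
    if not 0 < min_abundance < 1:
        raise ChemError("min_abundance must lie in (0, 1)")
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for el, n in sorted(species.formula.counts.items()):
        el_dist = _element_distribution(table[el], n, _prune)
        dist = [
            (m1 + m2, p1 * p2)
            for m1, p1 in dist
            for m2, p2 in el_dist
            if p1 * p2 >= _prune
        ]
    z = species.charge
    dist = [((m - z * ELECTRON_MASS_DA) / abs(z), p) for m, p in dist]
    merged = _merge_peaks(dist, merge_tol)
    retained = [(mz, ab) for mz, ab in merged if ab >= min_abundance]
    if not retained:  # keep at least the base peak for very spread patterns
        retained = [max(merged, key=lambda p: p[1])]
    return IsotopePattern(
        peaks=retained,
        merge_tol=merge_tol,
        min_abundance=min_abundance,
        retained_fraction=sum(ab for _, ab in merged),
        label=species.label,
    )


# ---------------------------------------------------------------------------
# Isotope-fit score
# ---------------------------------------------------------------------------

def sigma_fit(
    measured: Sequence[tuple[float, float]],
    theo: IsotopePattern,
    ppm_tol: float = 3.0,
) -> float:
    """Isotope-fit score: 0 is a perfect fit, small is good.

    The ``k = min(3, len(pattern))`` most abundant theoretical peaks are
    matched to the nearest measured centroid within ``ppm_tol``; both
    matched intensity vectors are normalized to unit sum and the score is
    ``1000 * sqrt(mean squared difference)``.  If any required theoretical
    peak has no measured partner the ``UNMATCHED`` sentinel (+inf) is
    returned, which fails every finite acceptance cap.

    The score is invariant to uniform intensity scaling of the measured
    spectrum, mirroring vendor isotope-fit statistics gated at <= 30.
    """
    if not measured:
        raise ChemError("measured peak list is empty")
    if not theo.peaks:
        raise ChemError("theoretical pattern is empty")
    if ppm_tol <= 0:
        raise ChemError("ppm_tol must be positive")
    k = min(3, len(theo.peaks))
    top = sorted(theo.peaks, key=lambda p: -p[1])[:k]
    theo_int: list[float] = []
    meas_int: list[float] = []
    for mz_t, ab_t in top:
        tol = mz_t * ppm_tol * 1e-6
        best = None
        for mz_m, i_m in measured:
            d = abs(mz_m - mz_t)
            if d <= tol and (best is None or d < best[0]):
                best = (d, i_m)
        if best is None:
            return UNMATCHED
        theo_int.append(ab_t)
        meas_int.append(best[1])
    st, sm = sum(theo_int), sum(meas_int)
    if sm <= 0:
        return UNMATCHED
    resid = sum(
        (im / sm - it / st) ** 2 for im, it in zip(meas_int, theo_int)
    )
    return 1000.0 * math.sqrt(resid / k)


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adduct:
    """An ionization rule: atoms added to the neutral molecule and the
    resulting charge, e.g. [M+H]+ or the NEDC-derived chloride [MCl2]-."""

    label: str
    add: Mapping[str, int]
    charge: int
    primary: bool = False

    def apply(self, neutral: Formula) -> IonSpecies:
        formula = neutral + Formula(dict(self.add)) if self.add else neutral
        return IonSpecies(formula=formula, charge=self.charge, label=self.label)

    def mass_shift(self, table: ElementIsotopeTable | None = None) -> float:
        """m/z offset relative to neutral monoisotopic mass M (for |z| = 1:
        m/z = M + shift)."""
        table = table or ElementIsotopeTable.default()
        added = sum(
            table.most_abundant_mass(el) * n for el, n in self.add.items()
        )
        return (added - self.charge * ELECTRON_MASS_DA) / abs(self.charge)


def load_adducts(path=None) -> dict[str, list[Adduct]]:
    """Load the adduct set for each polarity from JSON (defaults shipped:
    protonated/alkali/ammonium positives, chloride-anion negatives)."""
    if path is None:
        ref = resources.files("biosolid_msi.data") / "adducts.json"
        with resources.as_file(ref) as p:
            raw = json.loads(p.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return {
        pol: [Adduct(a["label"], a["add"], a["charge"], a.get("primary", False)) for a in entries]
        for pol, entries in raw.items()
    }


def metal_chloride_ion(
    metal: str, n_cl: int, table: ElementIsotopeTable | None = None
) -> IonSpecies:
    """Chlorinated heavy-metal anion [MCl_n]- as formed with excess
    chloride from the NEDC matrix."""
    return IonSpecies(
        formula=Formula({metal: 1, "Cl": n_cl}),
        charge=-1,
        label=f"[{metal}Cl{n_cl}]-",
    )
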