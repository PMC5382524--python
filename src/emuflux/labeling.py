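"""Measured-labeling handling: fragments, MS data containers and
natural-isotope-abundance correction.

A mass spectrometer reports the mass envelope of a derivatized fragment,
which mixes the biological 13C enrichment of the carbon backbone with the
natural heavy-isotope envelope of every other atom in the ion
(derivatization silicon, oxygens, nitrogens, ...). The correction here
deconvolves the latter: the natural mass-isotope distribution of the
non-backbone composition is convolved into a column-stochastic correction
matrix, and the biological MDV is recovered by nonnegative least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .core import MDV, ValidationError, formula_to_string, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "LabelData",
    "LCMSLabelData",
    "GCMSLabelData",
    "CEMSLabelData",
    "FragmentDB",
    "correction_matrix",
    "correct_mdv",
    "natural_abundances",
    "NATURAL_ABUNDANCE",
]

#: natural mass-isotope abundances per element, index = mass shift in Da
#: (IUPAC representative values)
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
}


def natural_abundances(overrides: dict | None = None) -> dict[str, tuple[float, ...]]:
    """The abundance table, optionally with per-element overrides."""
    table = dict(NATURAL_ABUNDANCE)
    if overrides:
        table.update({k: tuple(v) for k, v in overrides.items()})
    return table


@dataclass(frozen=True)
class Fragment:
    """An MS fragment: a measured carbon backbone plus everything else.

    ``formula`` is the full elemental composition of the ion;
    ``n_carbons`` the number of backbone carbons whose labeling is measured;
    ``formula_no_backbone`` the composition with those carbons removed
    (derivatization groups and heteroatoms), whose natural isotope envelope
    contaminates the measured mass distribution.
    """

    name: str
    abbreviation: str
    formula: str
    n_carbons: int
    formula_no_backbone: str = ""

    def __post_init__(self) -> None:
        comp = dict(parse_formula(self.formula))
        if self.n_carbons < 0:
            raise ValidationError(f"{self.name}: n_carbons must be >= 0")
        if comp.get("C", 0) < self.n_carbons:
            raise ValidationError(
                f"{self.name}: formula {self.formula} has fewer carbons than n_carbons"
            )
        expected = dict(comp)
        expected["C"] = expected.get("C", 0) - self.n_carbons
        if not expected["C"]:
            del expected["C"]
        given = dict(parse_formula(self.formula_no_backbone))
        if given != expected:
            raise ValidationError(
                f"{self.name}: formula_no_backbone {self.formula_no_backbone!r} is not "
                f"formula minus {self.n_carbons} backbone carbons "
                f"(expected {formula_to_string(list(expected.items()))!r})"
            )


def _element_envelope(element: str, count: int, table) -> np.ndarray:
    if element not in table:
        raise ValidationError(
            f"no natural-abundance data for element {element!r}; supported: "
            f"{sorted(table)}"
        )
    dist = np.asarray(table[element], dtype=float)
    out = np.array([1.0])
    for _ in range(count):
        out = np.convolve(out, dist)
    return out


def correction_matrix(
    fragment: Fragment, abundances: dict | None = None
) -> np.ndarray:
    """Square natural-abundance correction matrix of size ``n_carbons + 1``.

    Column *m* is the mass envelope observed when exactly *m* backbone
    carbons are labeled: the natural envelope of the non-backbone
    composition shifted down by *m* mass units, truncated to the measured
    window and renormalized, so the matrix is column-stochastic. In the
    no-heavy-isotope limit it reduces to the identity.
    """
    table = natural_abundances(abundances)
    envelope = np.array([1.0])
    for element, count in parse_formula(fragment.formula_no_backbone):
        envelope = np.convolve(envelope, _element_envelope(element, count, table))
    n = fragment.n_carbons
    M = np.zeros((n + 1, n + 1))
    for m in range(n + 1):
        col = np.zeros(n + 1)
        top = min(len(envelope), n + 1 - m)
        col[m : m + top] = envelope[:top]
        total = col.sum()
        if total <= 0:  # pragma: no cover - envelope always has mass at 0
            raise ValidationError(f"{fragment.name}: empty correction column {m}")
        M[:, m] = col / total
    return M


def correct_mdv(
    raw: MDV, fragment: Fragment, abundances: dict | None = None
) -> tuple[MDV, float]:
    """Remove the natural-isotope envelope from a measured MDV.

    Solves ``correction_matrix @ corrected = raw`` by nonnegative least
    squares (plain inversion can produce negative fractions on noisy data),
    renormalizes, and returns ``(corrected, residual)``. A residual above
    0.1 indicates a raw vector inconsistent with the fragment and is
    flagged with a warning.
    """
    if len(raw) != fragment.n_carbons + 1:
        raise ValidationError(
            f"{fragment.name}: raw MDV length {len(raw)} != n_carbons + 1"
        )
    M = correction_matrix(fragment, abundances)
    corrected, residual = scipy.optimize.nnls(M, raw.fractions)
    if residual > 0.1:
        logger.warning(
            "%s: natural-abundance correction residual %.3f; raw data inconsistent",
            fragment.name,
            residual,
        )
    return MDV(corrected, errors=raw.errors, normalize=True), float(residual)


# ---------------------------------------------------------------------------
# platform-specific containers
# ---------------------------------------------------------------------------


@dataclass
class LabelData:
    """A fragment's measured MDV with its natural-abundance-corrected form."""

    fragment: Fragment
    raw_mdv: MDV
    platform: str = "MS"
    abundances: dict | None = None
    corrected_mdv: MDV = field(init=False)
    correction_residual: float = field(init=False)

    def __post_init__(self) -> None:
        self.corrected_mdv, self.correction_residual = correct_mdv(
            self.raw_mdv, self.fragment, self.abundances
        )


class LCMSLabelData(LabelData):
    def __init__(self, fragment, raw_mdv, abundances=None):
        super().__init__(fragment, raw_mdv, platform="LCMS", abundances=abundances)


class GCMSLabelData(LabelData):
    def __init__(self, fragment, raw_mdv, abundances=None):
        super().__init__(fragment, raw_mdv, platform="GCMS", abundances=abundances)


class CEMSLabelData(LabelData):
    def __init__(self, fragment, raw_mdv, abundances=None):
        super().__init__(fragment, raw_mdv, platform="CEMS", abundances=abundances)


# ---------------------------------------------------------------------------
# fragment database
# ---------------------------------------------------------------------------


class FragmentDB:
    """Lookup of known MS fragments by name or abbreviation (case-insensitive).

    Ships seeded from an editable CSV with columns
    ``name, abbreviation, formula, n_carbons, formula_no_backbone``.
    """

    def __init__(self, fragments: list[Fragment]):
        self._by_key: dict[str, Fragment] = {}
        self.fragments = list(fragments)
        for frag in fragments:
            for key in (frag.name, frag.abbreviation):
                if key:
                    self._by_key[key.lower()] = frag

    @classmethod
    def from_csv(cls, path) -> "FragmentDB":
        import csv

        fragments = []
        with open(path) as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0].strip().lower() == "name":
                    continue
                name, abbrev, formula, n_carbons, no_backbone = (x.strip() for x in row[:5])
                fragments.append(
                    Fragment(name, abbrev, formula, int(n_carbons), no_backbone)
                )
        return cls(fragments)

    @classmethod
    def default(cls) -> "FragmentDB":
        from importlib import resources

        with resources.as_file(
            resources.files("emuflux").joinpath("data/fragments.csv")
        ) as path:
            return cls.from_csv(path)

    def lookup(self, name_or_abbrev: str) -> Fragment:
        key = name_or_abbrev.lower()
        frag = self._by_key.get(key)
        if frag is None:
            import difflib

            close = difflib.get_close_matches(key, list(self._by_key), n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            raise KeyError(f"unknown fragment {name_or_abbrev!r}{hint}")
        return frag
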