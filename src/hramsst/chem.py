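"""Elemental formulas, monoisotopic masses, adduct m/z, and the reference panel.

The mass-accuracy statistic used throughout the package is the signed
relative error in parts per million between an observed ion m/z and the
theoretical m/z of a known reference ion.  This module provides the
theoretical side: Hill-notation formula parsing, monoisotopic mass
summation, proton-transfer adduct arithmetic, and a bundled 13-compound
reference panel spanning both electrospray polarities.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "PROTON_MASS",
    "MONOISOTOPIC_MASS",
    "ElementalFormula",
    "AdductSpec",
    "PROTON_GAIN",
    "PROTON_LOSS",
    "ReferenceCompound",
    "CompoundPanel",
    "PanelFinding",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "default_panel",
    "load_panel",
    "validate_panel",
]

#: Mass of the proton in unified atomic mass units (CODATA 2018).
PROTON_MASS = 1.00727646

#: Monoisotopic (most abundant isotope) atomic masses in u.
#: Values from the AME2020 atomic mass evaluation / NIST atomic weights
#: compilation, truncated to 8-9 significant decimals.  Four-decimal
#: agreement of computed adduct m/z with published reference values
#: requires at least 5-6 decimals per element.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840316273,
    "Na": 22.9897692809,
    "Si": 27.97692653465,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Br": 78.9183371,
    "I": 126.904473,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically unsupported formula strings."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: element symbol -> positive atom count."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("empty formula is invalid")
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {element} must be a positive integer, got {n!r}")
        # freeze the mapping so the dataclass is hashable and immutable
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C8H10N4O2"``.

    An omitted count means one atom.  Repeated element tokens are summed.
    Raises :class:`FormulaError` for empty input, unknown element symbols,
    or text that is not a pure element-count sequence.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        if not match.group(0):
            break
        element, digits = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"malformed formula {text!r}")
    return ElementalFormula(counts)


def format_formula(formula: ElementalFormula) -> str:
    """Canonical Hill ordering: C first, H second, then alphabetical."""
    counts = formula.counts
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else [])
        ordered += sorted(e for e in counts if e not in ("C", "H"))
    else:
        ordered = sorted(counts)
    return "".join(e if counts[e] == 1 else f"{e}{counts[e]}" for e in ordered)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in u: sum of most-abundant-isotope masses."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items())


def _normalize_adduct_label(label: str) -> str:
    # tolerate the typographic minus variants that appear in published tables
    return label.replace("−", "-").replace("–", "-").strip()


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged proton-transfer adduct: [M+H]+ or [M-H]-."""

    label: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        if abs(abs(self.mass_delta) - PROTON_MASS) > 5e-7 and self.mass_delta != 0.0:
            raise ValueError(
                f"mass delta {self.mass_delta} is neither zero nor the proton mass"
            )

    @classmethod
    def from_label(cls, label: str) -> "AdductSpec":
        norm = _normalize_adduct_label(label)
        if norm == "+H":
            return PROTON_GAIN
        if norm == "-H":
            return PROTON_LOSS
        raise ValueError(f"unsupported adduct label: {label!r} (expected '+H' or '-H')")

    @property
    def polarity(self) -> str:
        return "POS" if self.charge > 0 else "NEG"


PROTON_GAIN = AdductSpec(label="+H", mass_delta=+PROTON_MASS, charge=+1)
PROTON_LOSS = AdductSpec(label="-H", mass_delta=-PROTON_MASS, charge=-1)


def adduct_mz(formula: ElementalFormula, adduct: AdductSpec) -> float:
    """Theoretical m/z of the adduct ion: (M + delta) / |z|."""
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    return (monoisotopic_mass(formula) + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in ppm; positive when observed is high."""
    if not theoretical_mz > 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical_mz}")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass(frozen=True)
class ReferenceCompound:
    """One reference-panel entry.

    ``expected_mz`` is the published/curated target m/z; ``erratum_note``
    marks entries whose published m/z is inconsistent with the published
    formula (the value is kept as curated, and validation warns).
    """

    name: str
    formula: ElementalFormula
    adduct: AdductSpec
    expected_mz: float
    nominal_label: int
    polarity: str
    log_kow: float | None = None
    cid: str | None = None
    cas: str | None = None
    erratum_note: str | None = None

    def __post_init__(self) -> None:
        if self.polarity != self.adduct.polarity:
            raise ValueError(
                f"{self.name}: polarity {self.polarity} inconsistent with adduct {self.adduct.label}"
            )

    @property
    def computed_mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)

    @property
    def is_erratum(self) -> bool:
        return bool(self.erratum_note)


@dataclass(frozen=True)
class CompoundPanel:
    compounds: tuple[ReferenceCompound, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique within a panel")
        object.__setattr__(self, "compounds", tuple(self.compounds))

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def by_polarity(self, polarity: str) -> tuple[ReferenceCompound, ...]:
        return tuple(c for c in self.compounds if c.polarity == polarity)

    def get(self, name: str) -> ReferenceCompound:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)


def _compound_from_row(row: Mapping[str, str]) -> ReferenceCompound:
    formula = parse_formula(row["formula"])
    adduct = AdductSpec.from_label(row["adduct"])
    expected_raw = (row.get("expected_mz") or "").strip()
    expected = float(expected_raw) if expected_raw else round(adduct_mz(formula, adduct), 4)
    nominal_raw = (row.get("nominal_label") or "").strip()
    nominal = int(nominal_raw) if nominal_raw else int(round(expected))
    polarity = (row.get("polarity") or adduct.polarity).strip().upper()

    def opt(key: str) -> str | None:
        value = (row.get(key) or "").strip()
        return value or None

    log_kow_raw = opt("log_kow")
    return ReferenceCompound(
        name=row["name"].strip(),
        formula=formula,
        adduct=adduct,
        expected_mz=expected,
        nominal_label=nominal,
        polarity=polarity,
        log_kow=float(log_kow_raw) if log_kow_raw else None,
        cid=opt("cid"),
        cas=opt("cas"),
        erratum_note=opt("erratum_note"),
    )


def load_panel(path, name: str | None = None) -> CompoundPanel:
    """Load a panel from CSV.

    Required columns: ``name, formula, adduct``.  Optional: ``polarity``
    (derived from the adduct when absent), ``expected_mz`` (computed when
    absent), ``nominal_label, log_kow, cid, cas, erratum_note``.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = {"name", "formula", "adduct"} - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
        compounds = [_compound_from_row(row) for row in reader]
    return CompoundPanel(compounds=tuple(compounds), name=name or str(path))


def default_panel() -> CompoundPanel:
    """The bundled 13-compound reference panel (8 positive, 5 negative)."""
    source = resources.files("hramsst.data").joinpath("reference_panel.csv")
    with resources.as_file(source) as path:
        return load_panel(path, name="default-13")


@dataclass(frozen=True)
class PanelFinding:
    """Advisory finding from panel validation; never an error."""

    kind: str  # coverage_gap | out_of_range | duplicate_mass | mass_mismatch
    polarity: str | None
    message: str


def validate_panel(
    panel: CompoundPanel,
    mz_min: float = 100.0,
    mz_max: float = 1000.0,
    max_gap: float = 200.0,
    edge_margin: float = 75.0,
    mass_tol: float = 0.0005,
) -> list[PanelFinding]:
    """Advisory panel-design checks.

    Reports per-polarity m/z coverage gaps wider than ``max_gap`` between
    adjacent compounds (the recommended density is one compound per
    100-200 m/z across the scan range), uncovered spans longer than
    ``edge_margin`` at either end of the scan range (a stricter rule,
    since the range ends are where calibrant coverage is thinnest),
    compounds outside the scan range, duplicate target masses, and
    entries whose curated m/z disagrees with the formula-derived value by
    more than ``mass_tol`` u.
    """
    if not mz_min < mz_max:
        raise ValueError("mz_min must be below mz_max")
    findings: list[PanelFinding] = []

    for compound in panel:
        delta = abs(compound.computed_mz - compound.expected_mz)
        if delta > mass_tol:
            tag = " (known erratum)" if compound.is_erratum else ""
            findings.append(
                PanelFinding(
                    kind="mass_mismatch",
                    polarity=compound.polarity,
                    message=(
                        f"{compound.name}: formula-derived m/z {compound.computed_mz:.4f} "
                        f"differs from curated {compound.expected_mz:.4f} by {delta:.4f} u{tag}"
                    ),
                )
            )
        if not (mz_min <= compound.expected_mz <= mz_max):
            findings.append(
                PanelFinding(
                    kind="out_of_range",
                    polarity=compound.polarity,
                    message=f"{compound.name}: m/z {compound.expected_mz:.4f} outside scan range "
                    f"[{mz_min:g}, {mz_max:g}]",
                )
            )

    for polarity in ("POS", "NEG"):
        masses = sorted(c.expected_mz for c in panel.by_polarity(polarity))
        if not masses:
            continue
        for lo, hi in zip(masses, masses[1:]):
            if hi - lo > max_gap:
                findings.append(
                    PanelFinding(
                        kind="coverage_gap",
                        polarity=polarity,
                        message=f"{polarity}: no compound between m/z {lo:.1f} and {hi:.1f} "
                        f"(gap {hi - lo:.1f} u exceeds {max_gap:g} u)",
                    )
                )
        if masses[0] - mz_min > edge_margin:
            findings.append(
                PanelFinding(
                    kind="coverage_gap",
                    polarity=polarity,
                    message=f"{polarity}: no compound between m/z {mz_min:.1f} and "
                    f"{masses[0]:.1f} at the low end of the scan range",
                )
            )
        if mz_max - masses[-1] > edge_margin:
            findings.append(
                PanelFinding(
                    kind="coverage_gap",
                    polarity=polarity,
                    message=f"{polarity}: no compound between m/z {masses[-1]:.1f} and "
                    f"{mz_max:.1f} at the high end of the scan range",
                )
            )
        for lo, hi in zip(masses, masses[1:]):
            if math.isclose(lo, hi, abs_tol=1e-4):
                findings.append(
                    PanelFinding(
                        kind="duplicate_mass",
                        polarity=polarity,
                        message=f"{polarity}: duplicate target m/z {lo:.4f}",
                    )
                )
    return findings
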