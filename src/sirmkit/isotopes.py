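"""Elemental-formula isotope arithmetic and MID natural-abundance correction.

GC-MS isotopologue intensities of a derivatized metabolite fragment mix two
signals: the tracer-derived labeling of the metabolite backbone and the
natural heavy-isotope background of every atom in the fragment (for silylated
fragments the 29/30Si isotopes dominate the M+1/M+2 background).  This module
builds the linear map from backbone-labeling states to observable isotopologue
patterns and inverts it by non-negative least squares, yielding the mass
isotopomer distribution (MID) attributable to tracer alone, plus the 13C
fractional enrichment derived from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "ABUNDANCE_TABLE_VERSION",
    "ISOTOPE_SHIFTS",
    "ElementalFormula",
    "IsotopePattern",
    "MIDVector",
    "CorrectionMatrix",
    "parse_formula",
    "element_pattern",
    "convolve",
    "natural_pattern",
    "build_correction_matrix",
    "correct_mid",
    "fractional_enrichment",
]

ABUNDANCE_TABLE_VERSION = "iupac-2013"

# Nominal mass shift -> abundance, per element.  Shift-0 entries are the
# complements of the heavy-isotope abundances.  P is monoisotopic; it appears
# in phosphorylated glycolytic intermediates (PEP, 3-PG).
ISOTOPE_SHIFTS: dict[str, dict[int, float]] = {
    "C": {0: 1.0 - 0.0107, 1: 0.0107},
    "H": {0: 1.0 - 0.000115, 1: 0.000115},
    "N": {0: 1.0 - 0.00364, 1: 0.00364},
    "O": {0: 1.0 - 0.00038 - 0.00205, 1: 0.00038, 2: 0.00205},
    "Si": {0: 1.0 - 0.04685 - 0.03092, 1: 0.04685, 2: 0.03092},
    "S": {0: 1.0 - 0.0075 - 0.0425, 1: 0.0075, 2: 0.0425},
    "P": {0: 1.0},
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or unsupported element."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element symbol -> positive atom count."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for el, n in self.counts.items():
            if el not in ISOTOPE_SHIFTS:
                raise FormulaError(f"unsupported element {el!r}")
            if not isinstance(n, int) or n <= 0:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def minus_carbons(self, j: int) -> "ElementalFormula":
        """Formula with ``j`` carbons removed (used per correction-matrix column)."""
        nc = self["C"]
        if j > nc:
            raise ValueError(f"cannot remove {j} carbons from formula with {nc}")
        counts = {el: n for el, n in self.counts.items() if el != "C"}
        if nc - j > 0:
            counts["C"] = nc - j
        return ElementalFormula(counts)

    def n_atoms(self) -> int:
        return sum(self.counts.values())


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C11H26NO3Si2"``.

    An absent count means 1.  Raises :class:`FormulaError` naming the
    offending token on malformed input or unsupported elements.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ISOTOPE_SHIFTS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


@dataclass
class IsotopePattern:
    """Abundance vector indexed by nominal mass shift 0..K, truncated at K."""

    abundances: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or self.abundances.size == 0:
            raise ValueError("abundance vector must be 1-D and non-empty")
        if np.any(self.abundances < -1e-15):
            raise ValueError("abundances must be non-negative")
        if self.abundances.sum() > 1.0 + 1e-12:
            raise ValueError("abundances sum above 1")

    @property
    def K(self) -> int:
        return self.abundances.size - 1

    def normalized(self) -> np.ndarray:
        s = self.abundances.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero pattern")
        return self.abundances / s


@dataclass
class MIDVector:
    """Tracer-attributable mass isotopomer distribution of one fragment."""

    metabolite: str
    fragment_id: str
    n_backbone: int
    fractions: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.size != self.n_backbone + 1:
            raise ValueError("MID length must be n_backbone + 1")
        if np.any(self.fractions < -1e-12):
            raise ValueError("MID fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("MID fractions must sum to 1")


@dataclass
class CorrectionMatrix:
    """Maps backbone-labeling state j=0..n to the observable pattern 0..K."""

    fragment_id: str
    matrix: np.ndarray
    n_backbone: int
    abundance_version: str = ABUNDANCE_TABLE_VERSION

    @property
    def K(self) -> int:
        return self.matrix.shape[0] - 1


def _single_atom_pattern(element: str, K: int) -> np.ndarray:
    try:
        shifts = ISOTOPE_SHIFTS[element]
    except KeyError:
        raise FormulaError(f"unsupported element {element!r}") from None
    out = np.zeros(K + 1)
    for shift, ab in shifts.items():
        if shift <= K:
            out[shift] += ab
    return out


def element_pattern(element: str, count: int, K: int) -> IsotopePattern:
    """Mass-shift distribution of ``count`` atoms of one element, truncated at K.

    The multinomial distribution of total shift is computed by repeated
    discrete convolution of the single-atom pattern.
    """
    if count < 0:
        raise ValueError("atom count must be >= 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    out = np.zeros(K + 1)
    out[0] = 1.0
    if count == 0:
        return IsotopePattern(out)
    single = _single_atom_pattern(element, K)
    for _ in range(count):
        out = np.convolve(out, single)[: K + 1]
    return IsotopePattern(out, truncated=out.sum() < 1.0 - 1e-12)


def convolve(a: IsotopePattern, b: IsotopePattern) -> IsotopePattern:
    """Discrete convolution of two patterns truncated at the shared K."""
    if a.K != b.K:
        raise ValueError(f"pattern length mismatch: K={a.K} vs K={b.K}")
    out = np.convolve(a.abundances, b.abundances)[: a.K + 1]
    return IsotopePattern(out, truncated=a.truncated or b.truncated or out.sum() < 1.0 - 1e-12)


def natural_pattern(f: ElementalFormula, K: int) -> IsotopePattern:
    """Natural heavy-isotope mass-shift pattern of a whole formula."""
    out = IsotopePattern(np.eye(1, K + 1, 0).ravel())
    for el, n in f.counts.items():
        out = convolve(out, element_pattern(el, n, K))
    return out


def build_correction_matrix(
    fragment: ElementalFormula,
    n_backbone: int,
    K: int | None = None,
    fragment_id: str = "",
) -> CorrectionMatrix:
    """Correction matrix for a fragment with ``n_backbone`` traceable carbons.

    Column j is the natural pattern of the fragment with j carbons pinned as
    13C: those carbons no longer draw from the natural 13C distribution but
    contribute a fixed shift of j, so the column is the natural pattern of the
    formula minus j carbons, shifted down by j rows.  K defaults to
    ``n_backbone + 3``, enough to capture the Si-driven tail.
    """
    nc = fragment["C"]
    if n_backbone > nc:
        raise ValueError(f"n_backbone={n_backbone} exceeds fragment carbons ({nc})")
    if n_backbone < 0:
        raise ValueError("n_backbone must be >= 0")
    if K is None:
        K = n_backbone + 3
    if K < n_backbone:
        raise ValueError("K must be >= n_backbone")
    cm = np.zeros((K + 1, n_backbone + 1))
    for j in range(n_backbone + 1):
        nat = natural_pattern(fragment.minus_carbons(j), K - j).abundances
        cm[j : j + nat.size, j] = nat
    return CorrectionMatrix(fragment_id=fragment_id, matrix=cm, n_backbone=n_backbone)


def correct_mid(
    measured: np.ndarray,
    cm: CorrectionMatrix,
    metabolite: str = "",
    fragment_id: str | None = None,
) -> MIDVector:
    """Natural-abundance-correct a raw isotopologue intensity vector.

    Solves ``measured ~ cm.matrix @ x`` with x >= 0 (non-negative least
    squares; plain inversion can return negative fractions on noisy data) and
    renormalizes x to the simplex.  The relative residual norm is kept on the
    result for QC.
    """
    y = np.asarray(measured, dtype=float)
    if y.ndim != 1 or y.size != cm.K + 1:
        raise ValueError(f"measured vector must have length K+1={cm.K + 1}, got {y.size}")
    if np.any(y < 0):
        raise ValueError("measured intensities must be non-negative")
    total = y.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector")
    x, rnorm = nnls(cm.matrix, y / total)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero MID")
    return MIDVector(
        metabolite=metabolite,
        fragment_id=fragment_id if fragment_id is not None else cm.fragment_id,
        n_backbone=cm.n_backbone,
        fractions=x / s,
        residual=float(rnorm),
    )


def fractional_enrichment(mid: MIDVector, convention: str = "atom") -> float:
    """13C fractional enrichment of a corrected MID.

    ``atom`` (default): sum_i i*m_i / n — the fraction of backbone carbon
    atoms that are 13C.  ``labeled``: 1 - M+0 — the fraction of molecules
    carrying at least one tracer carbon.  The two coincide for uniformly
    labeled molecules mixed with unlabeled ones.
    """
    if mid.n_backbone == 0:
        raise ValueError("fractional enrichment undefined for n_backbone = 0")
    if convention == "atom":
        i = np.arange(mid.fractions.size)
        return float(np.dot(i, mid.fractions) / mid.n_backbone)
    if convention == "labeled":
        return float(1.0 - mid.fractions[0])
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# fragment library and table-level plumbing

def load_fragment_library(path=None) -> "pandas.DataFrame":
    """Load a fragment library CSV (metabolite,fragment_id,formula,n_backbone).

    Defaults to the shipped TBDMS M-57 library covering the study's
    metabolite panel.  Adds a parsed ``formula_obj`` column.
    """
    import importlib.resources
    import pandas as pd

    if path is None:
        ref = importlib.resources.files("sirmkit").joinpath("data/fragment_library.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"metabolite", "fragment_id", "formula", "n_backbone"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragment library missing columns: {sorted(missing)}")
    df["formula_obj"] = df["formula"].map(parse_formula)
    return df


def correction_matrices(library) -> dict[str, CorrectionMatrix]:
    """One correction matrix per library metabolite (K = n_backbone + 3)."""
    out = {}
    for _, row in library.iterrows():
        out[row["metabolite"]] = build_correction_matrix(
            row["formula_obj"], int(row["n_backbone"]), fragment_id=row["fragment_id"]
        )
    return out


def correct_intensity_table(df, library) -> "pandas.DataFrame":
    """Natural-abundance-correct a long GC-MS isotopologue intensity table.

    ``df`` columns: sample_id, metabolite, shift, intensity (plus any
    metadata columns, which are carried through).  Returns one row per
    (sample, metabolite, shift) with the corrected MID fraction, a
    ``corrected`` flag, and both enrichment conventions repeated per group.
    """
    import pandas as pd

    cms = correction_matrices(library)
    meta_cols = [
        c for c in df.columns if c not in ("shift", "intensity", "value")
    ]
    rows = []
    for key, grp in df.groupby(["sample_id", "metabolite"], sort=False):
        _, met = key
        if met not in cms:
            raise ValueError(f"metabolite {met!r} not in fragment library")
        cm = cms[met]
        grp = grp.sort_values("shift")
        y = np.zeros(cm.K + 1)
        shifts = grp["shift"].to_numpy(dtype=int)
        if np.any(shifts > cm.K) or np.any(shifts < 0):
            raise ValueError(f"{met}: shift outside 0..{cm.K}")
        y[shifts] = grp["intensity"].to_numpy(dtype=float)
        mid = correct_mid(y, cm, metabolite=met)
        base = {c: grp[c].iloc[0] for c in meta_cols}
        e_atom = fractional_enrichment(mid, "atom")
        e_lab = fractional_enrichment(mid, "labeled")
        for k, frac in enumerate(mid.fractions):
            rows.append(
                base
                | {
                    "shift": k,
                    "value": float(frac),
                    "corrected": True,
                    "residual": mid.residual,
                    "enrichment_atom": e_atom,
                    "enrichment_labeled": e_lab,
                }
            )
    return pd.DataFrame(rows)
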