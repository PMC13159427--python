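"""Library matching and confidence grading of SSN clusters.

A deconvoluted cluster is annotated in three steps: its product ions are
matched against a library of diagnostic fragments per species/adduct, the
precursor candidates are narrowed by accurate FT mass inside the isolation
window, and the combined evidence is graded on a five-level MSI annotation
confidence scale (Level 5: accurate mass only, down to Level 1: confirmed
against a reference standard with orthogonal validation; Level 2 is the
SSN tier — fragmentation at every pixel, spatial clustering above a
threshold, and a library match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .msi_io import PeakList, ScanFilter

__all__ = [
    "AdductDef",
    "ADDUCTS",
    "LibraryEntry",
    "PrecursorMatch",
    "ClusterAnnotation",
    "monoisotopic_mass",
    "adduct_mz",
    "load_library",
    "demo_library_path",
    "match_precursor",
    "match_cluster",
    "annotate_cluster",
    "assign_confidence",
    "sodiated_pc_diagnostics",
]

ELECTRON_MASS = 0.000548579909  # Da


@dataclass(frozen=True)
class AdductDef:
    """A singly-charged cation adduct: name and monoisotopic mass shift.

    The shift includes the electron lost on cationization, e.g.
    +H = 1.007276 Da (proton), not 1.007825 Da (hydrogen atom).
    """

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly-charged (+1) adducts are supported")
        if not np.isfinite(self.mass_shift):
            raise ValueError("adduct mass shift must be finite")


def _cation_shift(element: str) -> float:
    return _ptmass.calculate_mass(formula=element) - ELECTRON_MASS


ADDUCTS: dict[str, AdductDef] = {
    "+H": AdductDef("+H", _cation_shift("H")),
    "+Na": AdductDef("+Na", _cation_shift("Na")),
    "+K": AdductDef("+K", _cation_shift("K")),
    "+Ag": AdductDef("+Ag", _cation_shift("Ag")),
}


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral elemental formula in Da.

    An empty formula weighs 0; unknown element symbols raise ValueError.
    """
    if not formula:
        return 0.0
    try:
        return float(_ptmass.calculate_mass(formula=formula))
    except Exception as exc:
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc


def adduct_mz(neutral_mass: float, adduct: AdductDef) -> float:
    """m/z of the cationized species (neutral mass + shift, charge +1)."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be nonnegative")
    return (neutral_mass + adduct.mass_shift) / adduct.charge


@dataclass(frozen=True)
class LibraryEntry:
    """One species/adduct with its diagnostic product ions.

    ``precursor_mz`` is derived from the formula and adduct at construction
    and re-validated on load, so a corrupted library row fails early.
    """

    species: str
    formula: str
    adduct: AdductDef
    precursor_mz: float
    diagnostic_ions: tuple[tuple[float, str], ...]
    lipid_class: str = ""

    def __post_init__(self) -> None:
        if not self.diagnostic_ions:
            raise ValueError(f"{self.species}: diagnostic ion list must be nonempty")
        expected = adduct_mz(monoisotopic_mass(self.formula), self.adduct)
        if abs(expected - self.precursor_mz) > 1e-4:
            raise ValueError(
                f"{self.species}: precursor m/z {self.precursor_mz:.5f} "
                f"inconsistent with formula+adduct ({expected:.5f})"
            )

    @classmethod
    def create(
        cls,
        species: str,
        formula: str,
        adduct: AdductDef | str,
        diagnostic_ions: Iterable[tuple[float, str]],
        lipid_class: str = "",
    ) -> "LibraryEntry":
        add = ADDUCTS[adduct] if isinstance(adduct, str) else adduct
        prec = adduct_mz(monoisotopic_mass(formula), add)
        return cls(
            species=species, formula=formula, adduct=add, precursor_mz=prec,
            diagnostic_ions=tuple((float(m), str(l)) for m, l in diagnostic_ions),
            lipid_class=lipid_class,
        )


@dataclass(frozen=True)
class PrecursorMatch:
    """An FT peak explained by a library precursor, with its mass error."""

    peak_mz: float
    entry: LibraryEntry
    ppm: float


@dataclass
class ClusterAnnotation:
    """Ranked annotation candidates for one cluster plus a confidence level."""

    cluster_id: str
    candidates: list[dict]
    confidence_level: Optional[int] = None


def load_library(path) -> list[LibraryEntry]:
    """Load a product-ion library from TSV.

    Columns: species, formula, adduct, class, diagnostic_mzs,
    diagnostic_labels — the last two semicolon-separated and aligned.
    The precursor-consistency invariant is checked for every row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species", "formula", "adduct", "diagnostic_mzs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library is missing columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        mzs = [float(x) for x in str(row["diagnostic_mzs"]).split(";") if x]
        labels = [x for x in str(row.get("diagnostic_labels", "")).split(";") if x]
        if len(labels) != len(mzs):
            labels = [f"frag{i + 1}" for i in range(len(mzs))]
        entries.append(
            LibraryEntry.create(
                species=row["species"],
                formula=row["formula"],
                adduct=row["adduct"],
                diagnostic_ions=list(zip(mzs, labels)),
                lipid_class=row.get("class", ""),
            )
        )
    return entries


def demo_library_path() -> str:
    """Path of the bundled synthetic demo library.

    The file is a constructed fixture: formulas and adducts are real, but
    the diagnostic-ion lists mix rule-derived and invented fragments.  It
    exists so the examples and tests run self-contained; it is not a
    curated experimental resource.
    """
    return str(resources.files("ssnmsi").joinpath("data/synthetic_demo_library.tsv"))


def match_precursor(
    ft_peaks: PeakList,
    window: ScanFilter,
    library: Sequence[LibraryEntry],
    ppm_tol: float = 3.0,
) -> list[PrecursorMatch]:
    """Library precursors explaining FT peaks inside an isolation window.

    Only peaks within center ± width/2 are considered; every library
    precursor within ``ppm_tol`` of such a peak is returned, ranked by
    absolute ppm error.  3 ppm is tight enough to separate isobars a few
    mDa apart around m/z 800.
    """
    if window.ms_level < 2:
        raise ValueError("precursor matching needs an MS² window filter")
    half = window.isolation_width / 2.0
    lo, hi = window.isolation_center - half, window.isolation_center + half
    matches = []
    for pk in np.asarray(ft_peaks.mz, dtype=float):
        if not (lo <= pk <= hi):
            continue
        for entry in library:
            ppm = (pk - entry.precursor_mz) / entry.precursor_mz * 1e6
            if abs(ppm) <= ppm_tol:
                matches.append(PrecursorMatch(peak_mz=float(pk), entry=entry, ppm=ppm))
    matches.sort(key=lambda m: abs(m.ppm))
    return matches


def match_cluster(
    cluster_ions: Iterable[float],
    entry: LibraryEntry,
    mz_tol: float = 0.3,
) -> tuple[int, int, float]:
    """Greedy nearest-match of a cluster's ions to an entry's diagnostics.

    Returns (matched diagnostics, total diagnostics, fraction of cluster
    ions explained).  Each cluster ion is used at most once.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    ions = sorted(float(m) for m in cluster_ions)
    total = len(entry.diagnostic_ions)
    used = [False] * len(ions)
    matched = 0
    for diag_mz, _ in entry.diagnostic_ions:
        best, best_d = None, mz_tol
        for i, ion in enumerate(ions):
            if used[i]:
                continue
            d = abs(ion - diag_mz)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used[best] = True
            matched += 1
    explained = (sum(used) / len(ions)) if ions else 0.0
    return matched, total, explained


def annotate_cluster(
    cluster_ions: Iterable[float],
    library: Sequence[LibraryEntry],
    window: Optional[ScanFilter] = None,
    ft_peaks: Optional[PeakList] = None,
    ppm_tol: float = 3.0,
    mz_tol: float = 0.3,
    cluster_id: str = "",
) -> ClusterAnnotation:
    """Rank library candidates for one cluster.

    Candidates are ranked lexicographically by (fraction of diagnostics
    matched, fraction of cluster explained, −|precursor ppm error|); ties
    survive in the ranked list rather than being broken silently.  When FT
    peaks and the window filter are supplied, precursor mass errors join
    the evidence; entries whose precursor falls outside the window are
    dropped.
    """
    ions = sorted(float(m) for m in cluster_ions)
    precursor_ppm: dict[str, float] = {}
    eligible = list(library)
    if window is not None:
        half = window.isolation_width / 2.0
        eligible = [
            e for e in library
            if abs(e.precursor_mz - window.isolation_center) <= half
        ]
        if ft_peaks is not None:
            for m in match_precursor(ft_peaks, window, eligible, ppm_tol):
                key = m.entry.species + m.entry.adduct.name
                if key not in precursor_ppm or abs(m.ppm) < abs(precursor_ppm[key]):
                    precursor_ppm[key] = m.ppm
    candidates = []
    for entry in eligible:
        matched, total, explained = match_cluster(ions, entry, mz_tol)
        if matched == 0:
            continue
        ppm = precursor_ppm.get(entry.species + entry.adduct.name)
        candidates.append(
            {
                "entry": entry,
                "matched_diag": matched,
                "total_diag": total,
                "cluster_explained": explained,
                "precursor_ppm": ppm,
            }
        )
    candidates.sort(
        key=lambda c: (
            -(c["matched_diag"] / c["total_diag"]),
            -c["cluster_explained"],
            abs(c["precursor_ppm"]) if c["precursor_ppm"] is not None else np.inf,
        )
    )
    return ClusterAnnotation(cluster_id=cluster_id, candidates=candidates)


def assign_confidence(
    accurate_mass: bool = False,
    ms2_some_pixels: bool = False,
    ms2_all_pixels: bool = False,
    cluster_above_threshold: bool = False,
    library_match: bool = False,
    standard_confirmed: bool = False,
    orthogonal_validation: bool = False,
    level4_rule: Optional[Callable[[dict], bool]] = None,
) -> int:
    """Grade annotation evidence on the five-level MSI confidence scale.

    Level 5: accurate mass only.  Level 3: accurate mass plus MS² from a
    few pixels.  Level 2: fragmentation at every pixel, product-ion
    clustering above the spatial-similarity threshold, and a library match.
    Level 1: Level-2 evidence confirmed against a reference standard with
    orthogonal validation.  Level 4 is never auto-assigned; pass a
    ``level4_rule`` predicate over the evidence flags to enable it.
    """
    if ms2_all_pixels and not ms2_some_pixels:
        raise ValueError(
            "inconsistent evidence: MS² at all pixels implies MS² at some pixels"
        )
    flags = {
        "accurate_mass": accurate_mass,
        "ms2_some_pixels": ms2_some_pixels,
        "ms2_all_pixels": ms2_all_pixels,
        "cluster_above_threshold": cluster_above_threshold,
        "library_match": library_match,
        "standard_confirmed": standard_confirmed,
        "orthogonal_validation": orthogonal_validation,
    }
    level2 = ms2_all_pixels and cluster_above_threshold and library_match
    if level2 and standard_confirmed and orthogonal_validation:
        return 1
    if level2:
        return 2
    if accurate_mass and ms2_some_pixels:
        return 3
    if level4_rule is not None and level4_rule(flags):
        return 4
    if accurate_mass:
        return 5
    raise ValueError("no gradable evidence: at least accurate mass is required")


# ---------------------------------------------------------------------------
# Rule-based diagnostic generation (sodiated/protonated PC helper)
# ---------------------------------------------------------------------------

_TRIMETHYLAMINE = monoisotopic_mass("C3H9N")  # 59.0735, head-group loss
_PHOSPHOCHOLINE = monoisotopic_mass("C5H14NO4P")  # 183.0660
_PROTONATED_HEAD = _PHOSPHOCHOLINE + ADDUCTS["+H"].mass_shift  # m/z 184.0733


def _fatty_acid_mass(carbons: int, double_bonds: int) -> float:
    return monoisotopic_mass(f"C{carbons}H{2 * carbons - 2 * double_bonds}O2")


def sodiated_pc_diagnostics(
    formula: str, chains: Sequence[tuple[int, int]]
) -> list[tuple[float, str]]:
    """Diagnostic fragments of a sodiated phosphatidylcholine.

    Head-group chemistry of [PC+Na]+ under collisional activation: loss of
    trimethylamine (−59.0735), loss of the phosphocholine head group
    (−183.0660), and — structure-resolving — combined loss of trimethylamine
    and each fatty acid, one per sn chain (carbons, double bonds).  This
    small rule set covers the sodiated PC species used in the examples; it
    is not a general lipid fragmentation engine.
    """
    prec = adduct_mz(monoisotopic_mass(formula), ADDUCTS["+Na"])
    out = [
        (prec - _TRIMETHYLAMINE, "-N(CH3)3"),
        (prec - _PHOSPHOCHOLINE, "-phosphocholine"),
    ]
    for carbons, dbs in chains:
        fa = _fatty_acid_mass(carbons, dbs)
        out.append(
            (prec - _TRIMETHYLAMINE - fa, f"-N(CH3)3-FA({carbons}:{dbs})")
        )
    return out


def protonated_pc_headgroup() -> tuple[float, str]:
    """The m/z 184.0733 phosphocholine head-group ion of [PC+H]+."""
    return (_PROTONATED_HEAD, "phosphocholine+H")
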