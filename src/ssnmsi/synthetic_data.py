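"""Ground-truthed synthetic MS²I runs.

Real tandem-MSI tissue data for this kind of pipeline is rarely deposited,
so the test bed is a phantom: named spatial regions stand in for anatomical
structures (a band for a fiber tract, a disk for a ventricle), each hosting
one or more species with a precursor m/z, an abundance and a fragment
spectrum.  Species sharing an isolation window are co-isolated — their MS²
spectra are chimeric wherever their regions overlap — which is exactly the
condition spatial similarity networking is built to untangle.

The simulator follows a PIA schedule (one FT survey scan plus the MS² scans
of the pixel's inclusion list, cycling N lists along x), applies shot noise,
additive baseline peaks and pixel dropout, and writes a centroided mzML run
together with a GroundTruth object recording which fragment belongs to which
species and what the expected cluster partition of every window is.
"""

from __future__ import annotations

import base64
import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .msi_io import PeakList, PixelGrid, ScanFilter, SpectrumRecord, uniform_line_breaks
from .pia_model import AcquisitionConfig, build_schedule

__all__ = [
    "Phantom",
    "SpeciesSpec",
    "NoiseModel",
    "GroundTruth",
    "RecoveryResult",
    "make_phantom",
    "simulate_dataset",
    "write_mzml",
    "evaluate_recovery",
    "demo_window_scenario",
]


@dataclass
class Phantom:
    """Named spatial regions on a pixel grid.

    Each region is a weight map in [0, 1]; the boolean mask is where the
    weight is positive.  Regions may overlap.  Shapes smaller than 4×4 are
    rejected — they cannot carry meaningful spatial structure.
    """

    shape: tuple[int, int]
    seed: int = 0
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape[0] < 4 or self.shape[1] < 4:
            raise ValueError("phantom shape must be at least 4x4")

    def mask(self, name: str) -> np.ndarray:
        return self.weights[name] > 0

    def region_names(self) -> list[str]:
        return list(self.weights)

    def _add(self, name: str, w: np.ndarray) -> "Phantom":
        self.weights[name] = np.clip(w.astype(float), 0.0, 1.0)
        return self

    def add_full(self, name: str, weight: float = 1.0) -> "Phantom":
        return self._add(name, np.full(self.shape, weight))

    def add_band(
        self,
        name: str,
        rows: tuple[int, int],
        weight: float = 1.0,
        gradient: Optional[tuple[float, float]] = None,
    ) -> "Phantom":
        """Horizontal band over rows [rows[0], rows[1])."""
        r0, r1 = rows
        if not (0 <= r0 < r1 <= self.shape[0]):
            raise ValueError(f"band rows {rows} outside phantom of shape {self.shape}")
        w = np.zeros(self.shape)
        if gradient is None:
            w[r0:r1, :] = weight
        else:
            lo, hi = gradient
            ramp = np.linspace(lo, hi, self.shape[1])[None, :]
            w[r0:r1, :] = weight * ramp
        return self._add(name, w)

    def add_disk(
        self, name: str, center: tuple[int, int], radius: float, weight: float = 1.0
    ) -> "Phantom":
        r, c = center
        if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
            raise ValueError(f"disk center {center} outside phantom of shape {self.shape}")
        rr, cc = np.ogrid[: self.shape[0], : self.shape[1]]
        w = np.where((rr - r) ** 2 + (cc - c) ** 2 <= radius**2, weight, 0.0)
        return self._add(name, w)

    def add_complement(self, name: str, *of: str, weight: float = 1.0) -> "Phantom":
        """Region covering every pixel not in any of the named regions."""
        covered = np.zeros(self.shape, dtype=bool)
        for other in of:
            covered |= self.mask(other)
        return self._add(name, np.where(covered, 0.0, weight))


def make_phantom(
    shape: tuple[int, int], region_specs: Sequence[dict], seed: int = 0
) -> Phantom:
    """Build a phantom from declarative region specs.

    Each spec is a dict with a ``name`` and a ``kind`` in
    {full, band, disk, complement} plus that kind's parameters.
    Deterministic given seed.
    """
    ph = Phantom(shape=tuple(shape), seed=seed)
    for spec in region_specs:
        spec = dict(spec)
        kind = spec.pop("kind")
        name = spec.pop("name")
        if kind == "full":
            ph.add_full(name, **spec)
        elif kind == "band":
            spec["rows"] = tuple(spec["rows"])
            ph.add_band(name, **spec)
        elif kind == "disk":
            spec["center"] = tuple(spec["center"])
            ph.add_disk(name, **spec)
        elif kind == "complement":
            ph.add_complement(name, *spec.pop("of"), **spec)
        else:
            raise ValueError(f"unknown region kind {kind!r}")
    return ph


@dataclass(frozen=True)
class SpeciesSpec:
    """One precursor species living in one phantom region.

    Fragments are (m/z, relative intensity] pairs with exactly one relative
    intensity of 1 (the base peak) and all fragment m/z below the precursor.
    """

    name: str
    precursor_mz: float
    window_center: float
    region: str
    abundance: float
    fragments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        frags = tuple((float(m), float(r)) for m, r in self.fragments)
        object.__setattr__(self, "fragments", frags)
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if any(m >= self.precursor_mz for m, _ in frags):
            raise ValueError(f"{self.name}: fragment m/z must be below the precursor")
        rels = [r for _, r in frags]
        if any(not (0 < r <= 1) for r in rels) or rels.count(1.0) != 1:
            raise ValueError(
                f"{self.name}: relative intensities must lie in (0, 1] with "
                "exactly one base peak at 1"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic perturbations of the ideal phantom signal.

    ``shot`` Poisson-samples every expected peak count.  ``baseline_level``
    is the mean number of additive baseline peaks per spectrum, drawn
    uniformly over the scan range with exponential intensities of scale
    ``baseline_scale``.  ``dropout_prob`` is the per-pixel probability that
    a low-intensity fragment (relative intensity ≤ ``dropout_max_rel``)
    goes unrecorded — the mechanism that leaves low-S/N ions as singlets at
    high similarity thresholds.
    """

    shot: bool = True
    baseline_level: float = 2.0
    baseline_scale: float = 30.0
    dropout_prob: float = 0.05
    dropout_max_rel: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.dropout_max_rel):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.baseline_level < 0 or self.baseline_scale < 0:
            raise ValueError("baseline parameters must be nonnegative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(shot=False, baseline_level=0.0, dropout_prob=0.0)


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic run."""

    window_species: dict[float, dict[str, list[float]]]
    species_region: dict[str, np.ndarray]
    grid: PixelGrid
    n_ms2_per_ft: int
    line_breaks: list[int]

    def expected_partition(self, window_center: float) -> list[set[float]]:
        """The true cluster partition of one window's fragment ions."""
        species = self._window(window_center)
        return [set(frags) for frags in species.values()]

    def fragment_to_species(self, window_center: float) -> dict[float, str]:
        out = {}
        for name, frags in self._window(window_center).items():
            for m in frags:
                out[m] = name
        return out

    def _window(self, center: float) -> dict[str, list[float]]:
        for w, species in self.window_species.items():
            if abs(w - center) < 1e-6:
                return species
        raise KeyError(f"no window at m/z {center}")

    def to_json(self, path) -> None:
        payload = {
            "window_species": {
                repr(w): species for w, species in self.window_species.items()
            },
            "species_region": {
                k: np.asarray(v, dtype=int).tolist()
                for k, v in self.species_region.items()
            },
            "grid": {
                "n_lines": self.grid.n_lines,
                "pixels_per_line_ms1": self.grid.pixels_per_line_ms1,
                "n_lists": self.grid.n_lists,
                "ft_pixel_x_um": self.grid.ft_pixel_x_um,
                "ft_pixel_y_um": self.grid.ft_pixel_y_um,
            },
            "n_ms2_per_ft": self.n_ms2_per_ft,
            "line_breaks": list(self.line_breaks),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            window_species={
                float(w): {k: [float(m) for m in v] for k, v in species.items()}
                for w, species in payload["window_species"].items()
            },
            species_region={
                k: np.asarray(v, dtype=bool)
                for k, v in payload["species_region"].items()
            },
            grid=PixelGrid(**payload["grid"]),
            n_ms2_per_ft=int(payload["n_ms2_per_ft"]),
            line_breaks=[int(b) for b in payload["line_breaks"]],
        )


@dataclass
class RecoveryResult:
    """How well a cluster set recovered the generating species."""

    species_jaccard: dict[str, float]
    exact_match: bool


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_FT_RANGE = (200.0, 900.0)
_RT_STEP_S = 0.04


def _draw_count(rng: np.random.Generator, expected: float, shot: bool) -> float:
    if expected <= 0:
        return 0.0
    return float(rng.poisson(expected)) if shot else float(expected)


def _baseline_peaks(
    rng: np.random.Generator, noise: NoiseModel, mz_range: tuple[float, float]
) -> list[tuple[float, float]]:
    if noise.baseline_level <= 0:
        return []
    k = int(rng.poisson(noise.baseline_level))
    out = []
    for _ in range(k):
        mz = float(rng.uniform(*mz_range))
        inten = float(rng.exponential(noise.baseline_scale))
        if inten > 0:
            out.append((round(mz, 4), inten))
    return out


def simulate_dataset(
    phantom: Phantom,
    species: Sequence[SpeciesSpec],
    acq: AcquisitionConfig,
    noise: NoiseModel,
    seed: int,
    out_path,
    truth_path=None,
) -> tuple[str, GroundTruth]:
    """Simulate one MS²I run and write it as mzML.

    Every pixel gets an FT survey scan holding each locally present species'
    precursor peak, followed by the MS² scans of the pixel's inclusion list;
    each MS² spectrum sums the fragments of all co-isolated species present
    at that pixel (chimeric by construction), perturbed by the noise model.
    Byte-reproducible given the seed; the ground truth is noise-independent.
    """
    if acq.inclusion_lists is None:
        raise ValueError("acquisition config must carry explicit inclusion lists")
    grid = PixelGrid(
        n_lines=phantom.shape[0],
        pixels_per_line_ms1=phantom.shape[1],
        n_lists=acq.n_lists,
        ft_pixel_x_um=acq.ft_pixel_x_um,
        ft_pixel_y_um=acq.ft_pixel_y_um,
    )
    all_windows = {w for lst in acq.inclusion_lists for w in lst}
    for sp in species:
        if not any(abs(sp.window_center - w) < 1e-6 for w in all_windows):
            raise ValueError(
                f"species {sp.name} targets window {sp.window_center} which is "
                "on no inclusion list"
            )
        if sp.region not in phantom.weights:
            raise ValueError(f"species {sp.name} references unknown region {sp.region!r}")

    rng = np.random.default_rng(noise.seed if noise.seed is not None else seed)
    schedule = build_schedule(acq, grid)
    records: list[SpectrumRecord] = []
    index = 0
    for entry in schedule:
        r, c = entry.row, entry.col
        # FT survey scan: precursors of every species present at this pixel.
        ft_pairs: list[tuple[float, float]] = []
        for sp in species:
            w = float(phantom.weights[sp.region][r, c])
            inten = _draw_count(rng, sp.abundance * w, noise.shot)
            if inten > 0:
                ft_pairs.append((round(sp.precursor_mz, 5), inten))
        ft_pairs += _baseline_peaks(rng, noise, _FT_RANGE)
        records.append(
            SpectrumRecord(
                index=index,
                filter=ScanFilter(analyzer="FT", ms_level=1),
                peaks=PeakList.from_pairs(ft_pairs),
                retention_time=index * _RT_STEP_S,
            )
        )
        index += 1
        # Targeted MS² scans of this pixel's inclusion list.
        for center in entry.window_centers:
            pairs: list[tuple[float, float]] = []
            for sp in species:
                if abs(sp.window_center - center) >= 1e-6:
                    continue
                w = float(phantom.weights[sp.region][r, c])
                for frag_mz, rel in sp.fragments:
                    dropped = (
                        rel <= noise.dropout_max_rel
                        and noise.dropout_prob > 0
                        and rng.random() < noise.dropout_prob
                    )
                    if dropped:
                        continue
                    inten = _draw_count(rng, sp.abundance * rel * w, noise.shot)
                    if inten > 0:
                        pairs.append((round(frag_mz, 4), inten))
            pairs += _baseline_peaks(rng, noise, (100.0, float(center)))
            records.append(
                SpectrumRecord(
                    index=index,
                    filter=ScanFilter(
                        analyzer="IT",
                        ms_level=2,
                        isolation_center=float(center),
                        isolation_width=acq.isolation_width_da,
                        activation="HCD",
                    ),
                    peaks=PeakList.from_pairs(pairs),
                    retention_time=index * _RT_STEP_S,
                )
            )
            index += 1

    write_mzml(records, out_path, run_id=f"synthetic_seed_{seed}")
    window_species: dict[float, dict[str, list[float]]] = {}
    for sp in species:
        window_species.setdefault(sp.window_center, {})[sp.name] = [
            round(m, 4) for m, _ in sp.fragments
        ]
    truth = GroundTruth(
        window_species=window_species,
        species_region={sp.name: phantom.mask(sp.region) for sp in species},
        grid=grid,
        n_ms2_per_ft=acq.n_ms2_per_ft,
        line_breaks=uniform_line_breaks(grid, acq.n_ms2_per_ft),
    )
    if truth_path is not None:
        truth.to_json(truth_path)
    return str(out_path), truth


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode()


def _spectrum_xml(rec: SpectrumRecord) -> str:
    f = rec.filter
    n = len(rec.peaks)
    parts = [
        f'<spectrum index="{rec.index}" id="scan={rec.index + 1}" defaultArrayLength="{n}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{f.ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
        '<scanList count="1"><scan>'
        '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{rec.retention_time:.6f}" unitCvRef="UO" unitAccession="UO:0000010" '
        'unitName="second"/></scan></scanList>',
    ]
    if f.ms_level >= 2:
        half = f.isolation_width / 2.0
        activation = {
            "HCD": ('MS:1000422', "beam-type collision-induced dissociation"),
            "CID": ('MS:1000133', "collision-induced dissociation"),
        }.get(f.activation)
        act_xml = (
            f'<cvParam cvRef="MS" accession="{activation[0]}" name="{activation[1]}" value=""/>'
            if activation
            else ""
        )
        parts.append(
            '<precursorList count="1"><precursor><isolationWindow>'
            '<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" '
            f'value="{f.isolation_center:.5f}"/>'
            '<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" '
            f'value="{half:.5f}"/>'
            '<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" '
            f'value="{half:.5f}"/>'
            "</isolationWindow><selectedIonList count=\"1\"><selectedIon>"
            '<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{f.isolation_center:.5f}"/>'
            f"</selectedIon></selectedIonList><activation>{act_xml}</activation>"
            "</precursor></precursorList>"
        )
    arrays = []
    for accession, name, payload in (
        ("MS:1000514", "m/z array", _encode_array(rec.peaks.mz)),
        ("MS:1000515", "intensity array", _encode_array(rec.peaks.intensity)),
    ):
        arrays.append(
            f'<binaryDataArray encodedLength="{len(payload)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>'
            f"<binary>{payload}</binary></binaryDataArray>"
        )
    parts.append(
        '<binaryDataArrayList count="2">' + "".join(arrays) + "</binaryDataArrayList>"
    )
    parts.append("</spectrum>")
    return "".join(parts)


def write_mzml(records: Sequence[SpectrumRecord], path, run_id: str = "run") -> str:
    """Write SpectrumRecords as a minimal, centroided mzML 1.1 document.

    Peak arrays are stored as uncompressed little-endian 64-bit floats, so
    m/z and intensity values survive the round trip bit-identically.
    """
    header = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        "</fileContent></fileDescription>"
        f'<run id="{run_id}">'
        f'<spectrumList count="{len(records)}">'
    )
    body = "".join(_spectrum_xml(rec) for rec in records)
    footer = "</spectrumList></run></mzML>"
    with open(path, "w") as fh:
        fh.write(header + body + footer)
    return str(path)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _match_count(truth_frags: Sequence[float], cluster_ions: Sequence[float], tol: float) -> int:
    """Greedy one-to-one matches between truth fragments and cluster ions."""
    used = [False] * len(cluster_ions)
    matched = 0
    for t in truth_frags:
        best, best_d = None, tol
        for i, ion in enumerate(cluster_ions):
            if used[i]:
                continue
            d = abs(ion - t)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used[best] = True
            matched += 1
    return matched


def evaluate_recovery(
    clusters, truth: GroundTruth, window_center: float, mz_tol: float = 0.3
) -> RecoveryResult:
    """Score a cluster set against the generator's ground truth.

    For each true species, the best-matching cluster's Jaccard index with
    the species' fragment set (m/z matched within ``mz_tol``).  The exact-
    match flag is true when the partition restricted to true fragment ions
    equals the generating partition — noise-only ions are ignored.
    """
    truth_sets = truth._window(window_center)
    species_jaccard: dict[str, float] = {}
    for name, frags in truth_sets.items():
        best = 0.0
        for cluster in clusters.clusters:
            ions = sorted(cluster)
            m = _match_count(frags, ions, mz_tol)
            union = len(frags) + len(ions) - m
            if union:
                best = max(best, m / union)
        species_jaccard[name] = best

    all_frags = sorted(truth.fragment_to_species(window_center))
    observed: list[frozenset] = []
    for cluster in clusters.clusters:
        members = set()
        for ion in cluster:
            dists = [abs(ion - t) for t in all_frags]
            if dists and min(dists) <= mz_tol:
                members.add(all_frags[int(np.argmin(dists))])
        if members:
            observed.append(frozenset(members))
    expected = {frozenset(s) for s in truth.expected_partition(window_center)}
    exact = set(observed) == expected and len(observed) == len(expected)
    return RecoveryResult(species_jaccard=species_jaccard, exact_match=exact)


# ---------------------------------------------------------------------------
# Demo scenario
# ---------------------------------------------------------------------------

def demo_window_scenario(
    shape: tuple[int, int] = (16, 24),
    seed: int = 0,
    abundance: float = 1000.0,
) -> tuple[Phantom, list[SpeciesSpec], AcquisitionConfig]:
    """Three co-isolated PC species in one 0.7 Da window at m/z 808.6.

    The cast mirrors a classic chimeric-window situation: a sodiated PC, a
    protonated PC isobar a few mDa away, and a potassiated ether PC, laid
    out on three disjoint regions (band, disk, remainder) so their product
    ions carry distinct spatial signatures.  Precursor m/z values are the
    theoretical monoisotopic adduct masses of the respective formulas.
    """
    phantom = make_phantom(
        shape,
        [
            {"name": "band", "kind": "band", "rows": (3, 7)},
            {"name": "disk", "kind": "disk",
             "center": (shape[0] * 3 // 4, shape[1] * 2 // 3), "radius": 3.5},
            {"name": "elsewhere", "kind": "complement", "of": ["band", "disk"],
             "weight": 0.8},
        ],
        seed=seed,
    )
    window = 808.6
    species = [
        SpeciesSpec(
            name="PC(18:1_18:1)+Na",
            precursor_mz=808.58268,
            window_center=window,
            region="band",
            abundance=abundance,
            fragments=((467.2533, 1.0), (749.5092, 0.35), (625.5166, 0.2)),
        ),
        SpeciesSpec(
            name="PC(38:5)+H",
            precursor_mz=808.58508,
            window_center=window,
            region="disk",
            abundance=abundance,
            fragments=((184.0733, 1.0), (577.5195, 0.45), (496.3402, 0.15)),
        ),
        SpeciesSpec(
            name="PC(O-36:3)+K",
            precursor_mz=808.56170,
            window_center=window,
            region="elsewhere",
            abundance=abundance,
            fragments=((739.4903, 1.0), (615.4998, 0.5), (441.2501, 0.2)),
        ),
    ]
    acq = AcquisitionConfig(
        n_lists=1,
        windows_per_list=1,
        isolation_width_da=0.7,
        inclusion_lists=((window,),),
    )
    return phantom, species, acq
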