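"""Centroided LC-MS run I/O, ion-chromatogram extraction, and apex picking.

Only MS1 centroid spectra are supported: the suitability statistic is the
m/z read at a chromatographic peak apex, which is only well defined for
centroided data.  The mzML reader is a focused implementation covering
the subset of the PSI mzML 1.1 standard this workflow needs (MS1 centroid
spectra, scan polarity, scan start time, 32/64-bit float binary arrays
with optional zlib compression); the writer produces minimal
standards-conformant mzML with uncompressed 64-bit float arrays.
"""

from __future__ import annotations

import base64
import os
import zlib
from dataclasses import dataclass
from xml.etree import ElementTree as ET

import numpy as np

from .chem import CompoundPanel, ppm_error

__all__ = [
    "Spectrum",
    "Run",
    "EIC",
    "ApexMeasurement",
    "MzMLReadError",
    "NoMatchingSpectraError",
    "ProfileModeError",
    "read_run",
    "write_mzml",
    "extract_eic",
    "find_apex",
    "measure_panel",
]


class MzMLReadError(RuntimeError):
    """Raised when an mzML file cannot be read or parsed."""


class NoMatchingSpectraError(MzMLReadError):
    """Raised when a file contains no MS1 spectra of the requested polarity."""


class ProfileModeError(MzMLReadError):
    """Raised when profile-mode spectra are encountered; only centroid data
    is supported (apex m/z readout requires centroided peaks)."""


@dataclass
class Spectrum:
    """One centroided MS1 scan."""

    scan_index: int
    rt_minutes: float
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("centroid m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.rt_minutes < 0:
            raise ValueError("retention time must be non-negative")


@dataclass
class Run:
    """An rt-ordered sequence of MS1 spectra from one injection."""

    spectra: list[Spectrum]
    source_id: str
    polarity: str

    def __post_init__(self) -> None:
        rts = [s.rt_minutes for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be ordered by non-decreasing retention time")
        for s in self.spectra:
            if s.polarity != self.polarity:
                raise ValueError("all spectra must share the run polarity")

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class EIC:
    """Extracted ion chromatogram within a ppm window around a target m/z.

    ``best_mz`` holds, per scan, the m/z of the most intense centroid
    inside the window (NaN when the window is empty in that scan).
    """

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray
    best_mz: np.ndarray


@dataclass
class ApexMeasurement:
    """Observed apex m/z and ppm error for one compound in one run."""

    compound_name: str
    expected_mz: float
    detected: bool
    apex_rt: float | None = None
    apex_mz: float | None = None
    apex_intensity: float | None = None
    ppm_error: float | None = None


def _normalize_polarity(polarity: str) -> str:
    pol = polarity.strip().upper()
    if pol in ("POS", "POSITIVE", "+"):
        return "POS"
    if pol in ("NEG", "NEGATIVE", "-"):
        return "NEG"
    raise ValueError(f"polarity must be POS or NEG, got {polarity!r}")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(array_el: ET.Element, path) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values) where kind is
    'mz', 'intensity' or None for other array types."""
    dtype: str | None = None
    compressed = False
    kind: str | None = None
    payload = ""
    for child in array_el.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    if kind is None:
        return None, np.empty(0)
    if dtype is None:
        raise MzMLReadError(f"{path}: binary array without a float-width cvParam")
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum_element(el: ET.Element, path) -> dict:
    info: dict = {"ms_level": None, "mode": None, "polarity": None, "rt_minutes": 0.0}
    for child in el.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                info["ms_level"] = int(child.get("value", "0"))
            elif acc == "MS:1000127":
                info["mode"] = "centroid"
            elif acc == "MS:1000128":
                info["mode"] = "profile"
            elif acc == "MS:1000130":
                info["polarity"] = "POS"
            elif acc == "MS:1000129":
                info["polarity"] = "NEG"
            elif acc == "MS:1000016":
                value = float(child.get("value", "0"))
                unit = (child.get("unitName") or "").lower()
                info["rt_minutes"] = value / 60.0 if unit in ("second", "s") else value
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(child, path)
            if kind:
                info[kind] = values
    return info


def read_run(path: str | os.PathLike, polarity: str) -> Run:
    """Read all MS1 centroid spectra of the requested polarity from mzML.

    Raises :class:`FileNotFoundError` for a missing file,
    :class:`ProfileModeError` if any matching spectrum is profile mode,
    :class:`NoMatchingSpectraError` when nothing matches, and
    :class:`MzMLReadError` for malformed XML.
    """
    pol = _normalize_polarity(polarity)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, element in context:
            if _local(element.tag) != "spectrum":
                continue
            record = _parse_spectrum_element(element, path)
            element.clear()
            if record["ms_level"] != 1 or record["polarity"] != pol:
                continue
            if record["mode"] == "profile":
                raise ProfileModeError(
                    f"{path}: profile-mode spectra are not supported; supply centroided data"
                )
            spectra.append(
                Spectrum(
                    scan_index=len(spectra),
                    rt_minutes=record["rt_minutes"],
                    mz=record.get("mz", np.empty(0)),
                    intensity=record.get("intensity", np.empty(0)),
                    polarity=pol,
                )
            )
    except MzMLReadError:
        raise
    except ET.ParseError as exc:
        raise MzMLReadError(f"failed to parse mzML file {path}: {exc}") from exc
    if not spectra:
        raise NoMatchingSpectraError(f"{path}: no MS1 {pol} centroid spectra found")
    spectra.sort(key=lambda s: s.rt_minutes)
    for i, s in enumerate(spectra):
        s.scan_index = i
    return Run(spectra=spectra, source_id=os.path.basename(str(path)), polarity=pol)


# --- minimal mzML writing -------------------------------------------------

_MS_CV = "http://psidev.info/ms/mzML/psi-ms.obo"
_UO_CV = "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"


def _cvparam(parent: ET.Element, accession: str, name: str, value: str = "", **units) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(units)
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, values: np.ndarray, accession: str, name: str) -> None:
    payload = base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")
    array = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(payload))})
    _cvparam(array, "MS:1000523", "64-bit float")
    _cvparam(array, "MS:1000576", "no compression")
    _cvparam(array, accession, name)
    ET.SubElement(array, "binary").text = payload


def write_mzml(run: Run, path: str | os.PathLike) -> None:
    """Write a run as centroided MS1 mzML readable by :func:`read_run`."""
    root = ET.Element(
        "mzML",
        {"xmlns": "http://psi.hupo.org/ms/mzml", "version": "1.1.0", "id": run.source_id or "run"},
    )
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {"id": "MS", "fullName": "PSI-MS", "URI": _MS_CV})
    ET.SubElement(cv_list, "cv", {"id": "UO", "fullName": "Unit Ontology", "URI": _UO_CV})
    file_desc = ET.SubElement(root, "fileDescription")
    content = ET.SubElement(file_desc, "fileContent")
    _cvparam(content, "MS:1000579", "MS1 spectrum")
    _cvparam(content, "MS:1000127", "centroid spectrum")

    run_el = ET.SubElement(root, "run", {"id": run.source_id or "run"})
    spec_list = ET.SubElement(run_el, "spectrumList", {"count": str(len(run.spectra))})
    pol_param = ("MS:1000130", "positive scan") if run.polarity == "POS" else ("MS:1000129", "negative scan")
    for spectrum in run.spectra:
        spec_el = ET.SubElement(
            spec_list,
            "spectrum",
            {
                "index": str(spectrum.scan_index),
                "id": f"scan={spectrum.scan_index + 1}",
                "defaultArrayLength": str(spectrum.mz.size),
            },
        )
        _cvparam(spec_el, "MS:1000511", "ms level", "1")
        _cvparam(spec_el, "MS:1000579", "MS1 spectrum")
        _cvparam(spec_el, "MS:1000127", "centroid spectrum")
        _cvparam(spec_el, *pol_param)
        scan_list = ET.SubElement(spec_el, "scanList", {"count": "1"})
        _cvparam(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cvparam(
            scan,
            "MS:1000016",
            "scan start time",
            f"{spectrum.rt_minutes:.6f}",
            unitCvRef="UO",
            unitAccession="UO:0000031",
            unitName="minute",
        )
        arrays = ET.SubElement(spec_el, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, spectrum.mz, "MS:1000514", "m/z array")
        _binary_array(arrays, spectrum.intensity, "MS:1000515", "intensity array")

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


# --- EIC extraction and apex picking --------------------------------------


def extract_eic(
    run: Run,
    target_mz: float,
    tol_ppm: float = 10.0,
    rt_range: tuple[float, float] | None = None,
) -> EIC:
    """Extract the ion chromatogram of ``target_mz`` within ±``tol_ppm``.

    Per scan, all centroid intensities in the window are summed and the
    most intense centroid's m/z recorded.  Scans with an empty window get
    zero intensity and a NaN best m/z.
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    lo = target_mz * (1.0 - tol_ppm * 1e-6)
    hi = target_mz * (1.0 + tol_ppm * 1e-6)
    rts, sums, bests = [], [], []
    for spectrum in run.spectra:
        if rt_range is not None and not (rt_range[0] <= spectrum.rt_minutes <= rt_range[1]):
            continue
        i0 = np.searchsorted(spectrum.mz, lo, side="left")
        i1 = np.searchsorted(spectrum.mz, hi, side="right")
        rts.append(spectrum.rt_minutes)
        if i1 > i0:
            window_int = spectrum.intensity[i0:i1]
            sums.append(float(window_int.sum()))
            bests.append(float(spectrum.mz[i0 + int(np.argmax(window_int))]))
        else:
            sums.append(0.0)
            bests.append(np.nan)
    return EIC(
        target_mz=target_mz,
        tol_ppm=tol_ppm,
        rt=np.asarray(rts),
        intensity=np.asarray(sums),
        best_mz=np.asarray(bests),
    )


def find_apex(eic: EIC, min_intensity: float = 1e4) -> tuple[float, float, float] | None:
    """Locate the chromatographic apex of an EIC.

    The apex is the scan with maximal summed window intensity (earliest
    scan on ties).  Returns ``(apex_rt, apex_mz, apex_intensity)`` or
    ``None`` when the maximum falls below ``min_intensity``.
    """
    if eic.intensity.size == 0:
        return None
    idx = int(np.argmax(eic.intensity))  # argmax takes the first maximum: ties -> earliest rt
    if eic.intensity[idx] < min_intensity:
        return None
    return float(eic.rt[idx]), float(eic.best_mz[idx]), float(eic.intensity[idx])


def _weighted_apex_mz(eic: EIC, apex_idx: int, rel_height: float = 0.5) -> float:
    """Intensity-weighted mean of per-scan best m/z over the peak top
    (scans contiguous with the apex above ``rel_height`` of its intensity)."""
    threshold = rel_height * eic.intensity[apex_idx]
    lo = apex_idx
    while lo > 0 and eic.intensity[lo - 1] >= threshold:
        lo -= 1
    hi = apex_idx
    while hi + 1 < eic.intensity.size and eic.intensity[hi + 1] >= threshold:
        hi += 1
    sel = slice(lo, hi + 1)
    weights = eic.intensity[sel]
    values = eic.best_mz[sel]
    ok = ~np.isnan(values)
    return float(np.average(values[ok], weights=weights[ok]))


def measure_panel(
    run: Run,
    panel: CompoundPanel,
    tol_ppm: float = 10.0,
    min_intensity: float = 1e4,
    rt_ranges: dict[str, tuple[float, float]] | None = None,
    mz_mode: str = "apex",
) -> list[ApexMeasurement]:
    """Measure apex m/z and ppm error for every panel compound matching
    the run polarity.

    ``mz_mode="apex"`` reads the most-intense-centroid m/z at the apex
    scan (the vendor-software convention); ``"weighted"`` instead takes an
    intensity-weighted mean across the peak top.  Undetected compounds are
    returned with ``detected=False`` and no error value.
    """
    if mz_mode not in ("apex", "weighted"):
        raise ValueError(f"mz_mode must be 'apex' or 'weighted', got {mz_mode!r}")
    measurements: list[ApexMeasurement] = []
    for compound in panel.by_polarity(run.polarity):
        rt_range = (rt_ranges or {}).get(compound.name)
        eic = extract_eic(run, compound.expected_mz, tol_ppm=tol_ppm, rt_range=rt_range)
        apex = find_apex(eic, min_intensity=min_intensity)
        if apex is None or np.isnan(apex[1]):
            measurements.append(
                ApexMeasurement(compound_name=compound.name, expected_mz=compound.expected_mz, detected=False)
            )
            continue
        apex_rt, apex_mz, apex_int = apex
        if mz_mode == "weighted":
            apex_mz = _weighted_apex_mz(eic, int(np.argmax(eic.intensity)))
        measurements.append(
            ApexMeasurement(
                compound_name=compound.name,
                expected_mz=compound.expected_mz,
                detected=True,
                apex_rt=apex_rt,
                apex_mz=apex_mz,
                apex_intensity=apex_int,
                ppm_error=ppm_error(apex_mz, compound.expected_mz),
            )
        )
    return measurements
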