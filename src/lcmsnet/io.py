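"""Reading and writing centroided LC-HRMS runs in mzML.

A run is held in memory as a :class:`Sample`: a point cloud of
(retention time, m/z, intensity) triples plus label/batch metadata.
Retention times are stored in seconds regardless of the units used on
disk.  Only MS1 centroid spectra are consumed; fragment (MS2+) scans in
data-dependent acquisition files are skipped.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
from lxml import etree

__all__ = ["PeakPoint", "Sample", "read_mzml", "write_mzml", "EmptySampleError"]


class EmptySampleError(ValueError):
    """Raised when an mzML file contains no usable MS1 centroid data."""


class PeakPoint(NamedTuple):
    """One centroided data point: retention time (s), m/z (Th), intensity."""

    rt: float
    mz: float
    intensity: float


@dataclass
class Sample:
    """One LC-HRMS run as a point cloud sorted by (rt, mz).

    Parameters
    ----------
    sample_id
        Opaque identifier for the run.
    rt, mz, intensity
        Parallel arrays of equal length.  ``rt`` in seconds (>= 0),
        ``mz`` in Thomson (> 0), ``intensity`` non-negative counts.
        Points are sorted lexicographically by (rt, mz) on construction.
    label
        Class label, or ``None`` for unlabeled data.
    batch_id
        Acquisition batch / instrument identifier, or ``None``.
    acquisition_span
        (rt_min, rt_max) of the acquisition in seconds.  Defaults to the
        span of the points themselves.
    """

    sample_id: str
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    label: str | None = None
    batch_id: str | None = None
    acquisition_span: tuple[float, float] | None = None
    _sorted: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if not (self.rt.shape == self.mz.shape == self.intensity.shape):
            raise ValueError("rt, mz and intensity must have equal length")
        if self.rt.size and (self.rt.min() < 0 or self.mz.min() <= 0 or self.intensity.min() < 0):
            raise ValueError("invalid point: require rt >= 0, mz > 0, intensity >= 0")
        if not self._sorted:
            order = np.lexsort((self.mz, self.rt))
            self.rt = self.rt[order]
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            self._sorted = True
        if self.acquisition_span is None:
            if self.rt.size:
                self.acquisition_span = (float(self.rt.min()), float(self.rt.max()))
            else:
                self.acquisition_span = (0.0, 0.0)
        lo, hi = self.acquisition_span
        if self.rt.size and (self.rt.min() < lo - 1e-9 or self.rt.max() > hi + 1e-9):
            raise ValueError("point retention times fall outside acquisition_span")

    @property
    def n_points(self) -> int:
        return int(self.rt.size)

    @property
    def points(self) -> Iterator[PeakPoint]:
        """Iterate over the points as :class:`PeakPoint` tuples."""
        for r, m, i in zip(self.rt, self.mz, self.intensity):
            yield PeakPoint(float(r), float(m), float(i))

    def replace_points(self, rt: np.ndarray, mz: np.ndarray, intensity: np.ndarray) -> "Sample":
        """New Sample with the same metadata but a different point cloud."""
        return Sample(
            sample_id=self.sample_id,
            rt=rt,
            mz=mz,
            intensity=intensity,
            label=self.label,
            batch_id=self.batch_id,
            acquisition_span=self.acquisition_span,
        )


# --------------------------------------------------------------------------
# mzML reading
# --------------------------------------------------------------------------
#
# Covers the centroided-MS1 subset of mzML 1.1: 32/64-bit float arrays,
# no compression or zlib, scan start time in minutes (the mzML default),
# seconds or milliseconds.

_RT_UNIT_TO_SECONDS = {
    None: 60.0,  # mzML default unit for scan start time is minutes
    "minute": 60.0,
    "second": 1.0,
    "seconds": 1.0,
    "millisecond": 1e-3,
}


def _decode_binary_array(bda: etree._Element, n_expected: int) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    for cv in bda.iterfind(f"{{{_MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000576":
            compressed = False
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    if binary is None or not binary.text:
        return np.zeros(n_expected, dtype=np.float64)
    raw = base64.b64decode(binary.text)
    if compressed:
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if values.size != n_expected:
        raise ValueError(f"binary array length {values.size} != defaultArrayLength {n_expected}")
    return values


def _parse_spectrum(spec: etree._Element) -> tuple[int, float, np.ndarray, np.ndarray]:
    """Return (ms_level, rt_seconds, mz, intensity) for one <spectrum>."""
    ms_level = 1
    for cv in spec.iterfind(f"{{{_MZML_NS}}}cvParam"):
        if cv.get("accession") == "MS:1000511":
            ms_level = int(cv.get("value"))
    rt = None
    for cv in spec.iterfind(f".//{{{_MZML_NS}}}scan/{{{_MZML_NS}}}cvParam"):
        if cv.get("accession") == "MS:1000016":
            unit = cv.get("unitName")
            if unit not in _RT_UNIT_TO_SECONDS:
                raise ValueError(f"unsupported scan start time unit: {unit!r}")
            rt = float(cv.get("value")) * _RT_UNIT_TO_SECONDS[unit]
    if rt is None:
        raise ValueError("spectrum lacks a scan start time (MS:1000016)")
    n = int(spec.get("defaultArrayLength", "0"))
    mz = inten = np.zeros(0)
    for bda in spec.iterfind(f".//{{{_MZML_NS}}}binaryDataArray"):
        names = {cv.get("accession") for cv in bda.iterfind(f"{{{_MZML_NS}}}cvParam")}
        if "MS:1000514" in names:
            mz = _decode_binary_array(bda, n)
        elif "MS:1000515" in names:
            inten = _decode_binary_array(bda, n)
    return ms_level, rt, mz, inten


def read_mzml(path: str | Path, sample_id: str | None = None) -> Sample:
    """Read a centroided mzML file into a :class:`Sample`.

    All MS1 spectra are pooled into one point cloud; zero-intensity
    entries are dropped and fragment-level (MS >= 2) spectra are skipped.
    Retention times are converted to seconds if stored in other units.

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptySampleError
        If the file contains no MS1 spectra or only empty ones.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    rts: list[np.ndarray] = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    scan_times: list[float] = []
    spectrum_tag = f"{{{_MZML_NS}}}spectrum"
    for _, spec in etree.iterparse(str(path), tag=spectrum_tag):
        ms_level, t, mz, inten = _parse_spectrum(spec)
        spec.clear()
        if ms_level != 1:
            continue
        scan_times.append(t)
        keep = inten > 0
        if keep.any():
            rts.append(np.full(int(keep.sum()), t))
            mzs.append(mz[keep])
            intens.append(inten[keep])
    if not scan_times:
        raise EmptySampleError(f"{path}: no MS1 spectra found")
    span = (min(scan_times), max(scan_times))
    if not rts:
        raise EmptySampleError(f"{path}: MS1 spectra contain no nonzero peaks")
    return Sample(
        sample_id=sample_id,
        rt=np.concatenate(rts),
        mz=np.concatenate(mzs),
        intensity=np.concatenate(intens),
        acquisition_span=span,
    )


# --------------------------------------------------------------------------
# mzML writing
# --------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_CV_MS = "MS"
_CV_UO = "UO"


def _cv(parent, accession: str, name: str, value: str = "", **extra) -> None:
    attrs = {"cvRef": _CV_MS, "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    etree.SubElement(parent, "cvParam", **attrs)


def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def write_mzml(sample: Sample, path: str | Path) -> None:
    """Write a :class:`Sample` as a centroided MS1 mzML file.

    Points sharing an identical retention time become one scan, with
    m/z ascending within the scan.  Retention times are written in
    seconds with an explicit unit annotation.

    Raises
    ------
    ValueError
        If the sample has no points.
    OSError
        If the path is not writable.
    """
    if sample.n_points == 0:
        raise ValueError("cannot write an empty sample to mzML")
    path = Path(path)

    root = etree.Element("mzML", nsmap={None: _MZML_NS}, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id=_CV_MS, fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id=_CV_UO, fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")

    software_list = etree.SubElement(root, "softwareList", count="1")
    sw = etree.SubElement(software_list, "software", id="lcmsnet", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="lcmsnet")

    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")

    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="lcmsnet")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run = etree.SubElement(root, "run", id=sample.sample_id, defaultInstrumentConfigurationRef="IC1")

    # group points by identical RT into scans (input already rt-sorted)
    unique_rt, first_idx = np.unique(sample.rt, return_index=True)
    boundaries = list(first_idx) + [sample.n_points]
    spectrum_list = etree.SubElement(
        run, "spectrumList", count=str(unique_rt.size), defaultDataProcessingRef="DP1"
    )
    for scan_index, scan_rt in enumerate(unique_rt):
        lo, hi = boundaries[scan_index], boundaries[scan_index + 1]
        mz = sample.mz[lo:hi]
        inten = sample.intensity[lo:hi]
        spec = etree.SubElement(
            spectrum_list, "spectrum",
            index=str(scan_index), id=f"scan={scan_index + 1}", defaultArrayLength=str(mz.size),
        )
        _cv(spec, "MS:1000579", "MS1 spectrum")
        _cv(spec, "MS:1000511", "ms level", value="1")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", value=repr(float(scan_rt)),
            unitCvRef=_CV_UO, unitAccession="UO:0000010", unitName="second",
        )
        badl = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, values in (
            ("MS:1000514", "m/z array", mz),
            ("MS:1000515", "intensity array", inten),
        ):
            encoded = _encode_array(values)
            bad = etree.SubElement(badl, "binaryDataArray", encodedLength=str(len(encoded)))
            _cv(bad, "MS:1000523", "64-bit float")
            _cv(bad, "MS:1000576", "no compression")
            _cv(bad, accession, name)
            etree.SubElement(bad, "binary").text = encoded

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
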