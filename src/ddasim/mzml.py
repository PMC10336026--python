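"""Minimal mzML output and fullscan mzML input.

The writer emits the smallest mzML dialect standard readers accept:
centroided spectra, 64-bit uncompressed (optionally zlib) binary arrays,
scan start times in seconds, and precursor isolation metadata (target
m/z, offsets, selected ion, intensity) on MS2 spectra.  The reader
resolves the same controlled-vocabulary terms by accession (ms level,
scan start time with its unit, binary array type/precision/compression,
precursor isolation); :func:`read_fullscan_mzml` yields only MS1 scans,
in retention-time order, logging how many MS2 spectra were skipped.
"""

from __future__ import annotations

import base64
import logging
import zlib
from typing import Iterator, Sequence
from xml.etree import ElementTree as ET
from xml.dom import minidom

import numpy as np

from .simulator import Scan

log = logging.getLogger(__name__)

_NS = "http://psi.hupo.org/ms/mzml"

# (accession, name) CV params used below
_CV = {
    "ms_level": ("MS:1000511", "ms level"),
    "ms1": ("MS:1000579", "MS1 spectrum"),
    "msn": ("MS:1000580", "MSn spectrum"),
    "centroid": ("MS:1000127", "centroid spectrum"),
    "scan_start": ("MS:1000016", "scan start time"),
    "mz_array": ("MS:1000514", "m/z array"),
    "int_array": ("MS:1000515", "intensity array"),
    "f64": ("MS:1000523", "64-bit float"),
    "no_comp": ("MS:1000576", "no compression"),
    "zlib": ("MS:1000574", "zlib compression"),
    "iso_target": ("MS:1000827", "isolation window target m/z"),
    "iso_lo": ("MS:1000828", "isolation window lower offset"),
    "iso_hi": ("MS:1000829", "isolation window upper offset"),
    "sel_mz": ("MS:1000744", "selected ion m/z"),
    "peak_int": ("MS:1000042", "peak intensity"),
    "hcd": ("MS:1000422", "beam-type collision-induced dissociation"),
}


def _cv(parent, key, value=None, unit=None):
    attrs = {"cvRef": "MS", "accession": _CV[key][0], "name": _CV[key][1],
             "value": "" if value is None else str(value)}
    if unit == "second":
        attrs.update(unitCvRef="UO", unitAccession="UO:0000010",
                     unitName="second")
    elif unit == "mz":
        attrs.update(unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent, values: Sequence[float], kind: str, compress: bool):
    raw = np.asarray(values, dtype="<f8").tobytes()
    data = zlib.compress(raw) if compress else raw
    encoded = base64.b64encode(data).decode("ascii")
    bda = ET.SubElement(parent, "binaryDataArray",
                        {"encodedLength": str(len(encoded))})
    _cv(bda, "f64")
    _cv(bda, "zlib" if compress else "no_comp")
    _cv(bda, kind)
    ET.SubElement(bda, "binary").text = encoded


def write_mzml(scans: Sequence[Scan], path, *, compress: bool = False) -> None:
    """Write clock-ordered scans as a valid mzML file.

    Read-back through pyteomics reproduces scan count, MS levels,
    retention times, and MS2 precursor targets exactly.
    """
    rts = [s.rt for s in scans]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError("scans must be clock-ordered")

    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {"id": "MS", "fullName":
                  "Proteomics Standards Initiative Mass Spectrometry Ontology",
                  "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cv_list, "cv", {"id": "UO", "fullName": "Unit Ontology",
                  "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    run = ET.SubElement(root, "run", {"id": "run1"})
    spec_list = ET.SubElement(run, "spectrumList", {"count": str(len(scans))})

    for i, scan in enumerate(scans):
        if scan.ms_level == 1:
            mzs = scan.mzs if scan.mzs is not None else np.empty(0)
            ints = scan.intensities if scan.intensities is not None else np.empty(0)
        else:
            # placeholder fragment content, deterministic from the precursor,
            # purely so the file is well-formed; fragment chemistry is out of
            # scope for scoring
            mzs = np.array([scan.precursor_mz * f for f in (0.3, 0.5, 0.8)])
            ints = np.full(3, scan.precursor_intensity or 0.0)
        spec = ET.SubElement(spec_list, "spectrum", {
            "index": str(i), "id": f"scan={i + 1}",
            "defaultArrayLength": str(len(mzs))})
        _cv(spec, "ms_level", scan.ms_level)
        _cv(spec, "ms1" if scan.ms_level == 1 else "msn")
        _cv(spec, "centroid")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        scan_el = ET.SubElement(scan_list, "scan")
        _cv(scan_el, "scan_start", repr(scan.rt), unit="second")
        if scan.ms_level == 2:
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            half = (scan.isolation_width or 0.0) / 2.0
            _cv(iso, "iso_target", repr(scan.precursor_mz), unit="mz")
            _cv(iso, "iso_lo", repr(half), unit="mz")
            _cv(iso, "iso_hi", repr(half), unit="mz")
            sil = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            sel = ET.SubElement(sil, "selectedIon")
            _cv(sel, "sel_mz", repr(scan.precursor_mz), unit="mz")
            _cv(sel, "peak_int", repr(scan.precursor_intensity or 0.0))
            act = ET.SubElement(prec, "activation")
            _cv(act, "hcd")
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, mzs, "mz_array", compress)
        _binary_array(arrays, ints, "int_array", compress)

    pretty = minidom.parseString(ET.tostring(root)).toprettyxml(indent="  ")
    with open(path, "w") as fh:
        fh.write(pretty)


def _iter_cv(element):
    for cv in element.iter(f"{{{_NS}}}cvParam"):
        yield cv.get("accession"), cv


def _decode_arrays(spec) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
        dtype = "<f8"
        compressed = False
        kind = None
        for acc, _cvp in _iter_cv(bda):
            if acc == "MS:1000521":          # 32-bit float
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        binary = bda.find(f"{{{_NS}}}binary")
        raw = base64.b64decode(binary.text or "")
        if compressed:
            raw = zlib.decompress(raw)
        if kind is not None:
            out[kind] = np.frombuffer(raw, dtype=dtype).astype("<f8")
    return out


def _parse_spectrum(spec) -> Scan:
    level = None
    for acc, cvp in _iter_cv(spec):
        if acc == "MS:1000511":
            level = int(cvp.get("value"))
            break
    if level is None:
        raise KeyError("ms level")
    rt = None
    for scan_el in spec.iter(f"{{{_NS}}}scan"):
        for acc, cvp in _iter_cv(scan_el):
            if acc == "MS:1000016":
                rt = float(cvp.get("value"))
                if cvp.get("unitName") == "minute":
                    rt *= 60.0
        break
    if rt is None:
        raise KeyError("scan start time")
    arrays = _decode_arrays(spec)
    if level == 1:
        return Scan(1, rt, mzs=arrays.get("mz", np.empty(0)),
                    intensities=arrays.get("intensity", np.empty(0)))
    prec_mz = prec_int = None
    lo = hi = 0.0
    for prec in spec.iter(f"{{{_NS}}}precursor"):
        for acc, cvp in _iter_cv(prec):
            if acc == "MS:1000744":
                prec_mz = float(cvp.get("value"))
            elif acc == "MS:1000042":
                prec_int = float(cvp.get("value"))
            elif acc == "MS:1000828":
                lo = float(cvp.get("value"))
            elif acc == "MS:1000829":
                hi = float(cvp.get("value"))
        break
    if prec_mz is None:
        raise KeyError("selected ion m/z")
    return Scan(2, rt, precursor_mz=prec_mz,
                precursor_intensity=prec_int or 0.0,
                isolation_width=lo + hi)


def read_mzml(path) -> list[Scan]:
    """Read all scans (MS1 and MS2) from an mzML file."""
    tree = ET.parse(str(path))
    scans: list[Scan] = []
    for idx, spec in enumerate(tree.getroot().iter(f"{{{_NS}}}spectrum")):
        try:
            scans.append(_parse_spectrum(spec))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"malformed spectrum at index {idx} in {path}: "
                             f"{exc}") from exc
    return scans


def read_fullscan_mzml(path) -> Iterator[Scan]:
    """Yield the MS1 scans of an mzML file in rt order, skipping MS2.

    Out-of-order files are re-sorted with a warning; the number of
    skipped MS2 spectra is logged.
    """
    scans = read_mzml(path)
    ms1 = [s for s in scans if s.ms_level == 1]
    n_ms2 = len(scans) - len(ms1)
    if n_ms2:
        log.info("skipped %d MS2 spectra in %s", n_ms2, path)
    rts = [s.rt for s in ms1]
    if any(b < a for a, b in zip(rts, rts[1:])):
        log.warning("MS1 scans in %s are not rt-ordered; re-sorting", path)
        ms1.sort(key=lambda s: s.rt)
    yield from ms1
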