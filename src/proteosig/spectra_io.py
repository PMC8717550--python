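"""Reading and writing DIA runs and search-result tables.

MGF is read and written through pyteomics.  mzML comes with a compact
reader/writer pair of its own: the reader is a namespace-agnostic XML
parser keyed on PSI-MS cvParam accessions (scan start time, isolation
window target/offsets, 32/64-bit zlib-or-plain binary arrays), and the
writer emits plain mzML 1.1 with uncompressed base64 64-bit arrays —
enough for the bundled simulator to exchange standard files with any
compliant tool.

All retention times are normalised to seconds on read (minute-valued scan
start times are converted using the file's unit annotation), because the
dual-indexing stage bins RT in seconds.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "MsmsScan",
    "RunManifest",
    "SchemaError",
    "read_run",
    "write_mzml",
    "write_mgf",
    "read_psm_table",
    "read_manifest",
    "write_manifest",
]


class SchemaError(ValueError):
    """A tabular input is missing required named columns."""


@dataclass
class MsmsScan:
    """One MS/MS event with its isolation metadata and centroided peak list."""

    run_id: str
    scan_number: int
    rt: float  # seconds
    isolation_center: float  # m/z
    isolation_width: float  # Th
    mz_array: np.ndarray
    intensity_array: np.ndarray
    ms_level: int = 2

    def __post_init__(self) -> None:
        self.mz_array = np.asarray(self.mz_array, dtype=float)
        self.intensity_array = np.asarray(self.intensity_array, dtype=float)
        if self.mz_array.shape != self.intensity_array.shape:
            raise ValueError(
                f"scan {self.scan_number}: m/z and intensity arrays differ "
                f"in length ({self.mz_array.size} vs {self.intensity_array.size})"
            )
        if self.mz_array.size > 1 and not np.all(np.diff(self.mz_array) > 0):
            raise ValueError(
                f"scan {self.scan_number}: m/z array must be strictly increasing"
            )
        if self.rt < 0:
            raise ValueError(f"scan {self.scan_number}: negative RT {self.rt}")

    @property
    def summed_intensity(self) -> float:
        return float(self.intensity_array.sum())


@dataclass
class RunManifest:
    """Per-run experiment metadata (one row of the experiment design)."""

    run_id: str
    path: str = ""
    mix: str = ""
    input_ng: float = float("nan")
    batch: str = ""
    plex: int = 10


# ---------------------------------------------------------------------------
# reading


def _scan_number_from_id(spectrum_id: str, fallback: int) -> int:
    m = re.search(r"scan=(\d+)", spectrum_id or "")
    return int(m.group(1)) if m else fallback


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, dict]:
    """accession -> {value, unit} for the direct cvParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = {
                "value": child.get("value"),
                "unit": child.get("unitName"),
            }
    return out


def _find_child(elem, name):
    for child in elem:
        if _local(child.tag) == name:
            return child
    return None


def _decode_binary_array(bda) -> np.ndarray | None:
    params = _cv_params(bda)
    binary = _find_child(bda, "binary")
    raw = base64.b64decode(binary.text or "") if binary is not None else b""
    if "MS:1000574" in params:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if "MS:1000514" in params:
        return "mz", values
    if "MS:1000515" in params:
        return "intensity", values
    return None, values


def _parse_spectrum(spec, run_id: str, idx: int):
    """Returns an MsmsScan, 'ms1', or None (missing metadata)."""
    params = _cv_params(spec)
    ms_level = int(params.get("MS:1000511", {}).get("value") or 0)
    if ms_level != 2:
        return "ms1"
    number = _scan_number_from_id(spec.get("id", ""), idx + 1)

    rt = None
    scan_list = _find_child(spec, "scanList")
    if scan_list is not None:
        scan_elem = _find_child(scan_list, "scan")
        if scan_elem is not None:
            sp = _cv_params(scan_elem)
            if "MS:1000016" in sp:
                rt = float(sp["MS:1000016"]["value"])
                if "minute" in str(sp["MS:1000016"]["unit"] or ""):
                    rt *= 60.0

    center = width = None
    plist = _find_child(spec, "precursorList")
    if plist is not None:
        prec = _find_child(plist, "precursor")
        iso = _find_child(prec, "isolationWindow") if prec is not None else None
        if iso is not None:
            ip = _cv_params(iso)
            if "MS:1000827" in ip:
                center = float(ip["MS:1000827"]["value"])
                lo = float(ip.get("MS:1000828", {}).get("value") or 0.0)
                hi = float(ip.get("MS:1000829", {}).get("value") or 0.0)
                width = lo + hi

    if rt is None or center is None:
        return None

    mz = inten = None
    bdal = _find_child(spec, "binaryDataArrayList")
    if bdal is not None:
        for bda in bdal:
            if _local(bda.tag) != "binaryDataArray":
                continue
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if mz is None or inten is None:
        return None
    return MsmsScan(
        run_id=run_id,
        scan_number=number,
        rt=rt,
        isolation_center=center,
        isolation_width=width if width and width > 0 else 0.0,
        mz_array=mz,
        intensity_array=inten,
    )


def _read_mzml(path: Path, run_id: str) -> list[MsmsScan]:
    scans: list[MsmsScan] = []
    n_ms1 = 0
    n_no_isolation = 0
    idx = 0
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        parsed = _parse_spectrum(elem, run_id, idx)
        idx += 1
        if parsed == "ms1":
            n_ms1 += 1
        elif parsed is None:
            n_no_isolation += 1
            logger.warning(
                "run %s: MS/MS spectrum %s lacks isolation/RT metadata; excluded",
                run_id,
                elem.get("id", idx),
            )
        else:
            scans.append(parsed)
        elem.clear()
    logger.info(
        "run %s: read %d MS/MS scans (%d MS1 dropped, %d excluded for "
        "missing isolation metadata)",
        run_id,
        len(scans),
        n_ms1,
        n_no_isolation,
    )
    return scans


def _read_mgf(path: Path, run_id: str, default_isolation_width: float) -> list[MsmsScan]:
    scans: list[MsmsScan] = []
    n_no_isolation = 0
    with _mgf.MGF(str(path)) as reader:
        for idx, spec in enumerate(reader):
            params = spec.get("params", {})
            pepmass = params.get("pepmass")
            rt = params.get("rtinseconds")
            if pepmass is None or rt is None:
                n_no_isolation += 1
                logger.warning(
                    "run %s: MGF spectrum %d lacks PEPMASS/RTINSECONDS; excluded",
                    run_id,
                    idx + 1,
                )
                continue
            center = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            number = int(params.get("scans", idx + 1))
            order = np.argsort(spec["m/z array"])
            scans.append(
                MsmsScan(
                    run_id=run_id,
                    scan_number=number,
                    rt=float(rt),
                    isolation_center=center,
                    isolation_width=default_isolation_width,
                    mz_array=np.asarray(spec["m/z array"])[order],
                    intensity_array=np.asarray(spec["intensity array"])[order],
                )
            )
    logger.info(
        "run %s: read %d MS/MS scans from MGF (%d excluded for missing metadata)",
        run_id,
        len(scans),
        n_no_isolation,
    )
    return scans


def read_run(
    path: str | Path,
    fmt: str | None = None,
    *,
    run_id: str | None = None,
    default_isolation_width: float = 6.0,
) -> list[MsmsScan]:
    """Read one DIA run into an acquisition-ordered list of MS/MS scans.

    MS1 spectra are dropped (counted in the log); MS/MS spectra without
    isolation metadata are excluded with a per-scan warning.  ``fmt`` is
    ``"mzml"`` or ``"mgf"``; by default it is inferred from the suffix.
    MGF carries no isolation width, so ``default_isolation_width`` is used.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"run file not found: {path}")
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    fmt = fmt.lower()
    rid = run_id if run_id is not None else path.stem
    if fmt == "mzml":
        scans = _read_mzml(path, rid)
    elif fmt == "mgf":
        scans = _read_mgf(path, rid, default_isolation_width)
    else:
        raise ValueError(f"unsupported run format: {fmt!r} (use mzML or MGF)")
    return scans


# ---------------------------------------------------------------------------
# writing

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value=None, unit=None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = str(value)
    if unit is not None:
        attrs.update(
            {"unitCvRef": unit[0], "unitAccession": unit[1], "unitName": unit[2]}
        )
    return ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent, values, accession, name, unit):
    data = np.asarray(values, dtype="<f8").tobytes()
    encoded = base64.b64encode(data).decode("ascii")
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(encoded))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    _cv(bda, accession, name, value="", unit=unit)
    ET.SubElement(bda, "binary").text = encoded


def write_mzml(scans: list[MsmsScan], path: str | Path, run_id: str | None = None) -> None:
    """Write scans as plain mzML 1.1 (uncompressed 64-bit base64 arrays).

    MS1 scans (``ms_level == 1``) are written without a precursor list; the
    output round-trips through any PSI-compliant reader, including
    :func:`read_run`.
    """
    rid = run_id or (scans[0].run_id if scans else "run")
    root = ET.Element(
        "mzML", {"xmlns": _MZML_NS, "version": "1.1.0", "id": rid}
    )
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(
        cvlist,
        "cv",
        {
            "id": "MS",
            "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
            "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
        },
    )
    ET.SubElement(
        cvlist,
        "cv",
        {
            "id": "UO",
            "fullName": "Unit Ontology",
            "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
        },
    )
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    run = ET.SubElement(root, "run", {"id": rid})
    speclist = ET.SubElement(run, "spectrumList", {"count": str(len(scans))})
    for i, scan in enumerate(scans):
        spec = ET.SubElement(
            speclist,
            "spectrum",
            {
                "index": str(i),
                "id": f"scan={scan.scan_number}",
                "defaultArrayLength": str(scan.mz_array.size),
            },
        )
        _cv(spec, "MS:1000511", "ms level", value=scan.ms_level)
        if scan.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scanlist = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scanlist, "MS:1000795", "no combination")
        sc = ET.SubElement(scanlist, "scan")
        _cv(
            sc,
            "MS:1000016",
            "scan start time",
            value=f"{scan.rt:.6f}",
            unit=("UO", "UO:0000010", "second"),
        )
        if scan.ms_level == 2:
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            half = scan.isolation_width / 2.0
            mz_unit = ("MS", "MS:1000040", "m/z")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                value=f"{scan.isolation_center:.6f}", unit=mz_unit)
            _cv(iso, "MS:1000828", "isolation window lower offset",
                value=f"{half:.6f}", unit=mz_unit)
            _cv(iso, "MS:1000829", "isolation window upper offset",
                value=f"{half:.6f}", unit=mz_unit)
            silist = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z",
                value=f"{scan.isolation_center:.6f}", unit=mz_unit)
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        bdal = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(bdal, scan.mz_array, "MS:1000514", "m/z array",
                      ("MS", "MS:1000040", "m/z"))
        _binary_array(bdal, scan.intensity_array, "MS:1000515", "intensity array",
                      ("MS", "MS:1000131", "number of detector counts"))
    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


def write_mgf(scans: list[MsmsScan], path: str | Path) -> None:
    """Write MS/MS scans to MGF (MS1 scans are skipped: MGF is MS/MS-only)."""
    entries = [
        {
            "m/z array": s.mz_array,
            "intensity array": s.intensity_array,
            "params": {
                "title": f"{s.run_id}.scan={s.scan_number}",
                "pepmass": s.isolation_center,
                "rtinseconds": s.rt,
                "scans": s.scan_number,
            },
        }
        for s in scans
        if s.ms_level == 2
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# tables

PSM_REQUIRED_COLUMNS = ("peptide", "protein", "q_value", "run_id", "scan_number")


def read_psm_table(path: str | Path, q_threshold: float = 0.01) -> pd.DataFrame:
    """Read a tab-separated PSM table and keep rows with q-value ≤ threshold.

    Required columns: peptide, protein, q_value, run_id, scan_number.
    The default 0.01 threshold mirrors the usual 1% PSM-level FDR filter.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"PSM table {path} missing required columns: {missing}")
    kept = df[df["q_value"] <= q_threshold].reset_index(drop=True)
    logger.info(
        "PSM table %s: %d/%d rows pass q <= %g", path, len(kept), len(df), q_threshold
    )
    return kept


MANIFEST_COLUMNS = ("run_id", "path", "mix", "input_ng", "batch", "plex")


def write_manifest(manifests: list[RunManifest], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in manifests])[list(MANIFEST_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path: str | Path) -> list[RunManifest]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} missing columns: {missing}")
    if df["run_id"].duplicated().any():
        raise SchemaError(f"manifest {path} has duplicate run_id values")
    return [
        RunManifest(
            run_id=str(r.run_id),
            path=str(r.path),
            mix=str(r.mix),
            input_ng=float(r.input_ng),
            batch=str(r.batch),
            plex=int(r.plex),
        )
        for r in df.itertuples()
    ]
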