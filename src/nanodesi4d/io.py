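"""Raw scan-stream IO and the persistent 4D (x, y, elution time, m/z) store.

Raw streams are read from mzML (a compact built-in reader covering the
base64/zlib float-array subset of the standard) or from a dependency-free
JSON "jsondump" dialect with the same contract.  The assembled image is
persisted as processed-mode imzML via pyimzml: standard imzML has only
(x, y, z) coordinates, so the elution-time scan slot is stored in the z
slot (1-based) with a JSON sidecar mapping slot -> seconds and carrying
the acquisition schedule.  This encoding is a declared dialect, flagged in
the sidecar metadata.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (AcquisitionSchedule, FormatError, MassSpectrum,
                   PixelRecord)

_ENCODING_FLAG = "z-slot-elution-time-v1"


# ---------------------------------------------------------------------------
# raw scan streams
# ---------------------------------------------------------------------------

def _decode_binary(elem, ns: str) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, 32/64-bit float, zlib or none."""
    accessions = {cv.get("accession") for cv in elem.findall(f"{ns}cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = elem.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        import zlib
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml(path) -> list[MassSpectrum]:
    """Minimal mzML reader covering the subset this package needs.

    Handles plain and indexed mzML with base64 float32/float64 arrays
    (optionally zlib-compressed), scan start times in seconds or minutes,
    ms level and the MS2 precursor isolation window.
    """
    import xml.etree.ElementTree as ET

    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(f"not an mzML file: {exc}") from exc
    root = tree.getroot()
    ns = root.tag[:root.tag.index("}") + 1] if root.tag.startswith("{") else ""

    scans = []
    for i, spectrum in enumerate(root.iter(f"{ns}spectrum")):
        params = {cv.get("accession"): cv
                  for cv in spectrum.findall(f"{ns}cvParam")}
        level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1

        t = None
        for scan in spectrum.iter(f"{ns}scan"):
            for cv in scan.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    t = float(cv.get("value"))
                    if "minute" in (cv.get("unitName") or ""):
                        t *= 60.0
        if t is None:
            raise FormatError(f"scan {i} lacks a scan start time")

        precursor = None
        for iso in spectrum.iter(f"{ns}isolationWindow"):
            center = lo = hi = None
            for cv in iso.findall(f"{ns}cvParam"):
                acc = cv.get("accession")
                if acc == "MS:1000827":
                    center = float(cv.get("value"))
                elif acc == "MS:1000828":
                    lo = float(cv.get("value"))
                elif acc == "MS:1000829":
                    hi = float(cv.get("value"))
            if center is not None:
                precursor = (center, ((lo or 0.0) + (hi or 0.0)) / 2.0)

        mz = inten = None
        for arr in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in accessions:
                mz = _decode_binary(arr, ns)
            elif "MS:1000515" in accessions:
                inten = _decode_binary(arr, ns)
        if mz is None or inten is None:
            raise FormatError(f"scan {i} lacks m/z or intensity arrays")
        scans.append(MassSpectrum(i, t, mz, inten, ms_level=level,
                                  precursor_window=precursor))
    return scans


def _read_jsondump(path) -> list[MassSpectrum]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not a jsondump file: {exc}") from exc
    scans = []
    for i, rec in enumerate(doc.get("scans", [])):
        precursor = rec.get("precursor_window")
        scans.append(MassSpectrum(
            scan_index=int(rec.get("scan_index", i)),
            time_s=float(rec["time_s"]),
            mz=np.asarray(rec["mz"], dtype=np.float64),
            intensity=np.asarray(rec["intensity"], dtype=np.float64),
            ms_level=int(rec.get("ms_level", 1)),
            precursor_window=tuple(precursor) if precursor else None))
    return scans


def read_scan_stream(path, format: Optional[str] = None) -> list[MassSpectrum]:
    """Read an ordered scan stream from mzML or a jsondump file.

    Scans must carry strictly increasing, unique start times; empty files
    and unknown formats raise :class:`FormatError` / ``ValueError``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"mzml": "mzml", ".mzml": "mzml",
                  ".json": "jsondump", ".jsondump": "jsondump"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if format == "mzml":
        scans = _read_mzml(path)
    elif format == "jsondump":
        scans = _read_jsondump(path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    if not scans:
        raise FormatError(f"{path} contains no scans")
    times = [s.time_s for s in scans]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise FormatError("scan times must be strictly increasing and unique")
    return scans


def write_jsondump(scans: Sequence[MassSpectrum], path) -> None:
    doc = {"format": "nanodesi4d-jsondump-v1", "scans": []}
    for s in scans:
        rec = {"scan_index": s.scan_index, "time_s": s.time_s,
               "ms_level": s.ms_level,
               "mz": np.asarray(s.mz).tolist(),
               "intensity": np.asarray(s.intensity).tolist()}
        if s.precursor_window is not None:
            rec["precursor_window"] = list(s.precursor_window)
        doc["scans"].append(rec)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode()


def write_mzml(scans: Sequence[MassSpectrum], path) -> None:
    """Write a minimal plain (non-indexed) mzML 1.1 file.

    Arrays are 64-bit little-endian floats, base64, no compression; scan
    start times carry the seconds unit.  Readable by pyteomics/ProteoWizard
    class readers; intended for simulator output and round-trip tests.
    """
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <cvList count="2">',
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '    <cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        '  </cvList>',
        '  <fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum"/>'
        '</fileContent></fileDescription>',
        '  <softwareList count="1"><software id="nanodesi4d" version="0.1.0"/></softwareList>',
        '  <instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>',
        '  <dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="nanodesi4d">'
        '<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML"/>'
        '</processingMethod></dataProcessing></dataProcessingList>',
        f'  <run id="run1" defaultInstrumentConfigurationRef="IC1">',
        f'    <spectrumList count="{len(scans)}" defaultDataProcessingRef="DP1">',
    ]
    for i, s in enumerate(scans):
        mzb, inb = _b64(s.mz), _b64(s.intensity)
        lines.append(
            f'      <spectrum index="{i}" id="scan={s.scan_index}" '
            f'defaultArrayLength="{s.mz.size}">')
        lines.append(f'        <cvParam cvRef="MS" accession="MS:1000511" '
                     f'name="ms level" value="{s.ms_level}"/>')
        lines.append('        <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum"/>')
        lines.append(
            '        <scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{s.time_s!r}" unitCvRef="UO" unitAccession="UO:0000010" '
            'unitName="second"/></scan></scanList>')
        if s.ms_level == 2 and s.precursor_window is not None:
            center, half = s.precursor_window
            lines.append(
                '        <precursorList count="1"><precursor><isolationWindow>'
                f'<cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{center!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{half!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{half!r}"/>'
                '</isolationWindow></precursor></precursorList>')
        lines.append('        <binaryDataArrayList count="2">')
        for accession, name, payload in (
                ("MS:1000514", "m/z array", mzb),
                ("MS:1000515", "intensity array", inb)):
            lines.append(
                f'          <binaryDataArray encodedLength="{len(payload)}">'
                f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
                f'<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
                f'<cvParam cvRef="MS" accession="{accession}" name="{name}"/>'
                f'<binary>{payload}</binary></binaryDataArray>')
        lines.append('        </binaryDataArrayList>')
        lines.append('      </spectrum>')
    lines += ['    </spectrumList>', '  </run>', '</mzML>', '']
    with open(path, "w") as fh:
        fh.write("\n".join(line for line in lines if line != ""))


# ---------------------------------------------------------------------------
# 4D image store
# ---------------------------------------------------------------------------

class Image4D:
    """The assembled 4D image: (x, y, elution-time slot, m/z).

    ``pixels`` maps (col, row) -> :class:`PixelRecord`; ``time_axis`` gives
    the elution time (s, relative to pixel contact) of each scan slot.
    """

    def __init__(self, pixels: dict, n_cols: int, n_rows: int,
                 schedule: AcquisitionSchedule, time_axis: np.ndarray,
                 metadata: Optional[dict] = None):
        self.pixels = dict(pixels)
        self.n_cols = int(n_cols)
        self.n_rows = int(n_rows)
        self.schedule = schedule
        self.time_axis = np.asarray(time_axis, dtype=float)
        self.metadata = dict(metadata or {})
        if self.time_axis.size > 1 and not np.all(np.diff(self.time_axis) > 0):
            raise ValueError("time_axis must be strictly increasing")
        for (c, r), px in self.pixels.items():
            if (c, r) != (px.col, px.row):
                raise ValueError("pixel key does not match its grid indices")
            if px.n_scans > self.time_axis.size:
                raise ValueError("pixel has more scans than time_axis slots")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def pixel(self, col: int, row: int) -> PixelRecord:
        return self.pixels[(col, row)]

    def pixel_list(self) -> list[PixelRecord]:
        """Pixels in row-major order."""
        return [self.pixels[k] for k in sorted(self.pixels, key=lambda k: (k[1], k[0]))]

    def equals(self, other: "Image4D") -> bool:
        """Structural equality: coordinates, arrays, times, schedule."""
        if (self.n_cols, self.n_rows) != (other.n_cols, other.n_rows):
            return False
        if set(self.pixels) != set(other.pixels):
            return False
        if not np.array_equal(self.time_axis, other.time_axis):
            return False
        if self.schedule.to_dict() != other.schedule.to_dict():
            return False
        for key, px in self.pixels.items():
            qx = other.pixels[key]
            if px.n_scans != qx.n_scans:
                return False
            for a, b in zip(px.spectra, qx.spectra):
                if (a.time_s != b.time_s or not np.array_equal(a.mz, b.mz)
                        or not np.array_equal(a.intensity, b.intensity)):
                    return False
        return True


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.json")


def write_imzml4d(image: Image4D, path) -> None:
    """Persist an :class:`Image4D` as processed-mode imzML (+ ibd + sidecar).

    Each scan becomes one imzML spectrum at 1-based coordinates
    (col+1, row+1, slot+1); the elution time axis and schedule go in the
    JSON sidecar since imzML has no time dimension.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    seen = set()
    for key in image.pixels:
        if key in seen:
            raise ValueError(f"coordinate collision at {key}")
        seen.add(key)
    path = Path(path)
    with ImzMLWriter(str(path), mz_dtype=np.float64,
                     intensity_dtype=np.float64, mode="processed") as writer:
        for px in image.pixel_list():
            for slot, spec in enumerate(px.spectra):
                writer.addSpectrum(spec.mz, spec.intensity,
                                   (px.col + 1, px.row + 1, slot + 1))
    sidecar = {
        "encoding": _ENCODING_FLAG,
        "n_cols": image.n_cols,
        "n_rows": image.n_rows,
        "schedule": image.schedule.to_dict(),
        "time_axis_s": image.time_axis.tolist(),
        "pixel_scan_times": {f"{c},{r}": [s.time_s for s in px.spectra]
                             for (c, r), px in image.pixels.items()},
        "pixel_contact_scan": {f"{c},{r}": px.contact_scan
                               for (c, r), px in image.pixels.items()},
        "ms_level": {f"{c},{r}": (px.spectra[0].ms_level if px.spectra else 1)
                     for (c, r), px in image.pixels.items()},
        "metadata": image.metadata,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)


def read_imzml4d(path) -> Image4D:
    """Reload an :class:`Image4D` written by :func:`write_imzml4d`."""
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing binary file {ibd}")
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    with open(meta_path) as fh:
        sidecar = json.load(fh)
    if sidecar.get("encoding") != _ENCODING_FLAG:
        raise FormatError("unknown 4D encoding dialect")
    schedule = AcquisitionSchedule.from_dict(sidecar["schedule"])
    time_axis = np.asarray(sidecar["time_axis_s"], dtype=float)

    parser = ImzMLParser(str(path))
    per_pixel: dict[tuple[int, int], dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for i, (x, y, z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        per_pixel.setdefault((x - 1, y - 1), {})[z - 1] = (
            np.asarray(mz, dtype=np.float64), np.asarray(inten, dtype=np.float64))
    pixels = {}
    for (c, r), slots in per_pixel.items():
        times = sidecar["pixel_scan_times"][f"{c},{r}"]
        level = int(sidecar.get("ms_level", {}).get(f"{c},{r}", 1))
        spectra = []
        for slot in sorted(slots):
            mz, inten = slots[slot]
            spectra.append(MassSpectrum(slot, float(times[slot]), mz, inten,
                                        ms_level=level))
        contact = int(sidecar.get("pixel_contact_scan", {}).get(f"{c},{r}", 0))
        pitch = (schedule.pitch_x_um, schedule.pitch_y_um)
        pixels[(c, r)] = PixelRecord(c, r, ((c + 0.5) * pitch[0], (r + 0.5) * pitch[1]),
                                     spectra, contact_scan=contact)
    return Image4D(pixels, sidecar["n_cols"], sidecar["n_rows"], schedule,
                   time_axis, metadata=sidecar.get("metadata", {}))
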