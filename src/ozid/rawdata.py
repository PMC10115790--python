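"""LC-MS1 raw-run access: mzML and a simple HDF5 run-store.

The HDF5 layout is ragged-array style::

    /scans/rt          (n_scans,)   float64, minutes, strictly increasing
    /scans/mz_offsets  (n_scans+1,) int64, slice bounds into the flat arrays
    /scans/mz          (n_points,)  float64, sorted ascending within a scan
    /scans/intensity   (n_points,)  float64, >= 0
    attrs: polarity ("positive"|"negative"), run_id

Datasets are written with ``track_times=False`` so identical runs produce
byte-identical files.  mzML is read through pyteomics; a minimal
uncompressed 64-bit mzML writer is provided so simulated runs can be
round-tripped through the standard format.  All retention times are
minutes and RT windows are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import h5py
import numpy as np
from pyteomics import mzml as pyteomics_mzml

__all__ = [
    "RawRun",
    "Chromatogram",
    "open_run",
    "write_run_store",
    "write_mzml",
    "extract_xic",
    "extract_ms1",
    "RunIOError",
    "EmptyWindowError",
]


class RunIOError(IOError):
    """Unreadable or unrecognized raw-run container."""


class EmptyWindowError(ValueError):
    """An RT window that selects no scans (distinct from an empty signal)."""


@dataclass
class Chromatogram:
    """Intensity vs retention time for one extracted m/z window."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly increasing")

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class RawRun:
    """An RT-ordered sequence of MS1 scans held in memory."""

    scans: list[tuple[float, np.ndarray, np.ndarray]]
    polarity: str = "positive"
    run_id: str = ""

    def __post_init__(self) -> None:
        rts = [s[0] for s in self.scans]
        if rts and not np.all(np.diff(rts) > 0):
            raise ValueError("scan retention times must be strictly increasing")
        clean = []
        for rt, mz, inten in self.scans:
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError("per-scan m/z and intensity lengths differ")
            if mz.size > 1 and np.any(np.diff(mz) < 0):
                raise ValueError("per-scan m/z arrays must be sorted")
            if np.any(inten < 0):
                raise ValueError("intensities must be >= 0")
            clean.append((float(rt), mz, inten))
        self.scans = clean

    @property
    def rts(self) -> np.ndarray:
        return np.array([s[0] for s in self.scans])

    def scan_indices_in(self, rt_min: float, rt_max: float) -> np.ndarray:
        rts = self.rts
        return np.where((rts >= rt_min) & (rts < rt_max))[0]


def open_run(path: str | Path) -> RawRun:
    """Read an mzML file or HDF5 run-store (selected by extension), MS1 only."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        return _read_run_store(path)
    if suffix == ".mzml":
        return _read_mzml(path)
    raise RunIOError(f"unrecognized raw-run extension {suffix!r} (expected .mzML or .h5)")


def _read_run_store(path: Path) -> RawRun:
    try:
        with h5py.File(path, "r") as f:
            rt = f["scans/rt"][...]
            offsets = f["scans/mz_offsets"][...]
            mz = f["scans/mz"][...]
            inten = f["scans/intensity"][...]
            polarity = f.attrs.get("polarity", "positive")
            run_id = f.attrs.get("run_id", "")
    except (OSError, KeyError) as exc:
        raise RunIOError(f"cannot read HDF5 run-store {path}: {exc}") from exc
    scans = [
        (float(rt[i]), mz[offsets[i] : offsets[i + 1]], inten[offsets[i] : offsets[i + 1]])
        for i in range(rt.size)
    ]
    return RawRun(scans, polarity=str(polarity), run_id=str(run_id))


def _read_mzml(path: Path) -> RawRun:
    try:
        return _read_mzml_pyteomics(path)
    except RunIOError:
        raise
    except Exception:
        # pyteomics >= 5 needs the optional psims package for PSI formats;
        # fall back to a minimal built-in parser (MS1, uncompressed or
        # zlib-compressed 32/64-bit float arrays)
        return _read_mzml_builtin(path)


def _read_mzml_pyteomics(path: Path) -> RawRun:
    scans = []
    polarity = "positive"
    with pyteomics_mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            if "negative scan" in spec:
                polarity = "negative"
            rt = spec["scanList"]["scan"][0]["scan start time"]
            unit = getattr(rt, "unit_info", "minute")
            rt_min = float(rt) / 60.0 if unit in ("second", "seconds") else float(rt)
            scans.append(
                (rt_min, np.asarray(spec["m/z array"]), np.asarray(spec["intensity array"]))
            )
    if not scans:
        raise RunIOError(f"mzML {path} contains no MS1 scans")
    scans.sort(key=lambda s: s[0])
    return RawRun(scans, polarity=polarity, run_id=path.stem)


def _decode_binary(elem, ns: str) -> np.ndarray:
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.findall(f"{ns}cvParam")
    }
    raw_text = elem.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(raw_text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml_builtin(path: Path) -> RawRun:
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise RunIOError(f"cannot read mzML {path}: {exc}") from exc
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    scans = []
    polarity = "positive"
    for spectrum in root.iter(f"{ns}spectrum"):
        params = {
            cv.get("accession"): cv for cv in spectrum.findall(f"{ns}cvParam")
        }
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", ""):
            continue
        if "MS:1000129" in params:
            polarity = "negative"
        rt_min = None
        for scan in spectrum.iter(f"{ns}scan"):
            for cv in scan.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    value = float(cv.get("value"))
                    unit = cv.get("unitName", "minute")
                    rt_min = value / 60.0 if unit in ("second", "seconds") else value
        if rt_min is None:
            continue
        mz = inten = None
        for arr in spectrum.iter(f"{ns}binaryDataArray"):
            acc = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                mz = _decode_binary(arr, ns)
            elif "MS:1000515" in acc:
                inten = _decode_binary(arr, ns)
        if mz is None or inten is None:
            continue
        scans.append((rt_min, mz, inten))
    if not scans:
        raise RunIOError(f"mzML {path} contains no readable MS1 scans")
    scans.sort(key=lambda s: s[0])
    return RawRun(scans, polarity=polarity, run_id=path.stem)


def write_run_store(run: RawRun, path: str | Path) -> None:
    """Write the HDF5 run-store; byte-deterministic for identical runs."""
    path = Path(path)
    offsets = np.zeros(len(run.scans) + 1, dtype=np.int64)
    for i, (_, mz, _) in enumerate(run.scans):
        offsets[i + 1] = offsets[i] + mz.size
    flat_mz = np.concatenate([s[1] for s in run.scans]) if run.scans else np.empty(0)
    flat_in = np.concatenate([s[2] for s in run.scans]) if run.scans else np.empty(0)
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("scans", track_order=True)
        kw = dict(track_times=False)
        g.create_dataset("rt", data=run.rts, **kw)
        g.create_dataset("mz_offsets", data=offsets, **kw)
        g.create_dataset("mz", data=flat_mz, **kw)
        g.create_dataset("intensity", data=flat_in, **kw)
        f.attrs["polarity"] = run.polarity
        f.attrs["run_id"] = run.run_id


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def write_mzml(run: RawRun, path: str | Path) -> None:
    """Write a minimal uncompressed 64-bit mzML (readable by pyteomics)."""
    path = Path(path)
    pol_cv = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if run.polarity == "positive"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    )
    spectra = []
    for i, (rt, mz, inten) in enumerate(run.scans):
        mz64, in64 = _b64(mz), _b64(inten)
        spectra.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        {pol_cv}
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "".join(spectra)
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{escape(run.run_id)}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{escape(run.run_id) or 'run'}">
    <spectrumList count="{len(run.scans)}" defaultDataProcessingRef="dp">{body}
    </spectrumList>
  </run>
</mzML>
"""
    path.write_text(doc)


def extract_xic(
    run: RawRun, mz: float, tol: float, rt_min: float, rt_max: float
) -> Chromatogram:
    """XIC: per scan in [rt_min, rt_max), sum intensity with |m/z - mz| <= tol.

    Scans with no points in the window contribute zeros; an RT range that
    overlaps no scans yields an empty chromatogram.
    """
    if tol <= 0:
        raise ValueError("m/z tolerance must be > 0")
    idx = run.scan_indices_in(rt_min, rt_max)
    rts = np.empty(idx.size)
    intensities = np.empty(idx.size)
    for k, i in enumerate(idx):
        rt, scan_mz, scan_in = run.scans[i]
        lo = np.searchsorted(scan_mz, mz - tol, side="left")
        hi = np.searchsorted(scan_mz, mz + tol, side="right")
        rts[k] = rt
        intensities[k] = scan_in[lo:hi].sum()
    return Chromatogram(rts, intensities)


def extract_ms1(
    run: RawRun, rt_min: float, rt_max: float, mz_min: float, mz_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-summed spectrum over scans in [rt_min, rt_max), sliced to m/z range.

    Points at identical m/z across scans are summed (profile data on a
    shared grid); distinct m/z values are kept as separate points.  Raises
    :class:`EmptyWindowError` if the RT window selects no scans.
    """
    idx = run.scan_indices_in(rt_min, rt_max)
    if idx.size == 0:
        raise EmptyWindowError(f"RT window [{rt_min}, {rt_max}) selects no scans")
    mzs, ins = [], []
    for i in idx:
        _, scan_mz, scan_in = run.scans[i]
        lo = np.searchsorted(scan_mz, mz_min, side="left")
        hi = np.searchsorted(scan_mz, mz_max, side="right")
        mzs.append(scan_mz[lo:hi])
        ins.append(scan_in[lo:hi])
    all_mz = np.concatenate(mzs)
    all_in = np.concatenate(ins)
    if all_mz.size == 0:
        return np.empty(0), np.empty(0)
    uniq, inverse = np.unique(all_mz, return_inverse=True)
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, all_in)
    return uniq, summed
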