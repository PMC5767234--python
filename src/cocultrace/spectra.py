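"""Centroided-spectrum I/O and isotopologue-ladder extraction.

Spectra are read either from mzML (via pyteomics) or from a simple delimited
table; a minimal mzML writer is provided so synthetic data can round-trip
through the open XML format.  Extraction sums, per nominal mass shift i, the
peak intensity found within a tolerance of ``target m/z + i * 1.003355`` over
all MS1 spectra inside a retention-time window — the M+0..M+N ladder of a
tracer experiment.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .chem import ElementalFormula
from .isotopes import C13_C12_SPACING

__all__ = [
    "CentroidSpectrum",
    "FeatureTarget",
    "IsotopologueMeasurement",
    "read_spectra",
    "write_spectra",
    "extract_isotopologues",
]


@dataclass
class CentroidSpectrum:
    """One centroided mass spectrum."""

    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class FeatureTarget:
    """A feature to extract: monoisotopic m/z, RT, polarity and formula."""

    feature_id: str
    mz: float
    rt_min: float
    polarity: str
    formula: ElementalFormula
    adduct: str = "M-H"


@dataclass
class IsotopologueMeasurement:
    """Raw isotopologue intensity ladder m0..mN for one feature in one sample."""

    feature_id: str
    sample_id: str
    intensities: np.ndarray
    timepoint: int | None = None
    group: str | None = None
    condition: str | None = None
    empty: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)


# ---------------------------------------------------------------------------
# I/O

def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitName="minute"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mzlen}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mzdata}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{intlen}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{intdata}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_PRECURSOR = """        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{pmz}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_spectra(spectra: list[CentroidSpectrum], path: str | Path) -> None:
    """Write spectra to mzML (``.mzml``) or a delimited table (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        with open(path, "w") as fh:
            fh.write(_MZML_HEADER.format(count=len(spectra)))
            for i, sp in enumerate(spectra):
                mzdata = _encode_array(sp.mz)
                intdata = _encode_array(sp.intensity)
                precursor = (
                    _MZML_PRECURSOR.format(pmz=sp.precursor_mz)
                    if sp.precursor_mz is not None
                    else ""
                )
                fh.write(
                    _MZML_SPECTRUM.format(
                        index=i,
                        npeaks=len(sp),
                        ms_level=sp.ms_level,
                        rt=escape(repr(sp.rt_min)),
                        precursor=precursor,
                        mzlen=len(mzdata),
                        mzdata=mzdata,
                        intlen=len(intdata),
                        intdata=intdata,
                    )
                )
            fh.write(_MZML_FOOTER)
    else:
        rows = []
        for i, sp in enumerate(spectra):
            for mz, inten in zip(sp.mz, sp.intensity):
                rows.append(
                    dict(
                        spectrum=i,
                        rt_min=sp.rt_min,
                        ms_level=sp.ms_level,
                        precursor_mz=sp.precursor_mz if sp.precursor_mz is not None else "",
                        mz=mz,
                        intensity=inten,
                    )
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _decode_binary(node, ns: str) -> np.ndarray:
    accessions = {
        p.get("accession") for p in node.findall(f"{ns}cvParam")
    }
    text = node.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[CentroidSpectrum]:
    """Compact reader for centroided mzML (64/32-bit float, zlib or plain)."""
    import xml.etree.ElementTree as ET

    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise IOError(f"{path}: malformed mzML ({exc})") from exc
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    spectra = []
    for sp in root.iter(f"{ns}spectrum"):
        params = {p.get("accession"): p.get("value") for p in sp.findall(f"{ns}cvParam")}
        ms_level = int(params.get("MS:1000511", 1))
        rt = 0.0
        scan = sp.find(f"{ns}scanList/{ns}scan")
        if scan is not None:
            for p in scan.findall(f"{ns}cvParam"):
                if p.get("accession") == "MS:1000016":
                    rt = float(p.get("value"))
                    if p.get("unitName", "minute").lower() == "second":
                        rt /= 60.0
        pmz = None
        for p in sp.iter(f"{ns}cvParam"):
            if p.get("accession") == "MS:1000744":
                pmz = float(p.get("value"))
        arrays = {}
        for bda in sp.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            accs = {p.get("accession") for p in bda.findall(f"{ns}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary(bda, ns)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary(bda, ns)
        if "mz" not in arrays or "intensity" not in arrays:
            raise IOError(f"{path}: spectrum without m/z or intensity array")
        spectra.append(
            CentroidSpectrum(
                rt_min=rt,
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                ms_level=ms_level,
                precursor_mz=pmz,
            )
        )
    return spectra


def _read_table(path: Path) -> list[CentroidSpectrum]:
    df = pd.read_csv(path, sep="\t")
    required = {"spectrum", "rt_min", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise IOError(f"{path}: missing spectrum-table columns {sorted(missing)}")
    spectra = []
    for _, grp in df.groupby("spectrum", sort=True):
        grp = grp.sort_values("mz")
        pmz = None
        if "precursor_mz" in grp and pd.notna(grp["precursor_mz"].iloc[0]):
            pmz = float(grp["precursor_mz"].iloc[0])
        spectra.append(
            CentroidSpectrum(
                rt_min=float(grp["rt_min"].iloc[0]),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                ms_level=int(grp["ms_level"].iloc[0]) if "ms_level" in grp else 1,
                precursor_mz=pmz,
            )
        )
    return spectra


def read_spectra(path: str | Path, format: str | None = None) -> list[CentroidSpectrum]:
    """Read centroid spectra from mzML or a delimited table, sorted by RT.

    ``format`` may be ``"mzml"`` or ``"table"``; by default it is inferred
    from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise IOError(f"empty spectrum file: {path}")
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "table"
    if format == "mzml":
        spectra = _read_mzml(path)
    elif format == "table":
        spectra = _read_table(path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    return sorted(spectra, key=lambda s: s.rt_min)


# ---------------------------------------------------------------------------
# Extraction

def extract_isotopologues(
    spectra: list[CentroidSpectrum],
    target: FeatureTarget,
    mz_tol_ppm: float = 10.0,
    rt_window_min: float = 0.2,
    sample_id: str = "",
) -> IsotopologueMeasurement:
    """Extract the M+0..M+N isotopologue intensity ladder of a target feature.

    For each nominal shift i in 0..N the intensities of MS1 peaks within
    ``mz_tol_ppm`` of ``target.mz + i * 1.003355`` are summed across all
    spectra whose RT lies within ``rt_window_min`` of the target RT.  A peak
    lying within tolerance of several ladder slots is assigned to the nearest
    slot, ties broken toward lower i.  If no spectrum falls in the RT window
    the measurement is returned flagged empty rather than raising.
    """
    n = target.formula.n_carbon
    if n < 1:
        raise ValueError("target formula must contain at least one carbon")
    ladder = target.mz + np.arange(n + 1) * C13_C12_SPACING
    tol = ladder * mz_tol_ppm * 1e-6
    out = np.zeros(n + 1)
    seen = False
    for sp in spectra:
        if sp.ms_level != 1 or abs(sp.rt_min - target.rt_min) > rt_window_min:
            continue
        seen = True
        if len(sp) == 0:
            continue
        # nearest ladder slot per peak; ties toward lower i via side="left"
        idx = np.searchsorted(ladder, sp.mz)
        for k, mz in enumerate(sp.mz):
            best_i, best_d = -1, np.inf
            for i in (idx[k] - 1, idx[k]):
                if 0 <= i <= n:
                    d = abs(mz - ladder[i])
                    if d < best_d - 1e-12:
                        best_i, best_d = i, d
            if best_i >= 0 and best_d <= tol[best_i]:
                out[best_i] += sp.intensity[k]
    return IsotopologueMeasurement(
        feature_id=target.feature_id,
        sample_id=sample_id,
        intensities=out,
        empty=not seen,
    )
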