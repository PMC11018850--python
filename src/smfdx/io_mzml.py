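"""Minimal mzML subset I/O for single-scan profile spectra.

Covers the pieces of the PSI mzML 1.1 schema this package needs: one MS1
spectrum per file with uncompressed (or zlib-compressed) 32/64-bit float
m/z and intensity arrays, identified by the standard cvParam accessions.
It is not a general mzML implementation.
"""

from __future__ import annotations

import base64
import zlib
import xml.etree.ElementTree as ET

import numpy as np

from .exceptions import SpectrumParseError

_NS = "http://psi.hupo.org/ms/mzml"

# cvParam accessions (PSI-MS controlled vocabulary)
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"

_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="{ns}" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len_mz}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{b64_mz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len_int}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{b64_int}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(path, mz, intensity, run_id: str = "sample") -> None:
    """Write one profile spectrum as a minimal mzML file (64-bit, uncompressed)."""
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if mz.shape != intensity.shape:
        raise SpectrumParseError("m/z and intensity arrays differ in length")
    b64_mz = base64.b64encode(mz.tobytes()).decode()
    b64_int = base64.b64encode(intensity.tobytes()).decode()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            _TEMPLATE.format(
                ns=_NS,
                run_id=run_id,
                n=mz.size,
                len_mz=len(b64_mz),
                b64_mz=b64_mz,
                len_int=len(b64_int),
                b64_int=b64_int,
            )
        )


def _decode_array(bda) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")}
    binary = bda.find(f"{{{_NS}}}binary")
    if binary is None or binary.text is None:
        raise SpectrumParseError("binaryDataArray without <binary> payload")
    raw = base64.b64decode(binary.text)
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    if _ACC_FLOAT32 in accessions:
        dtype = "<f4"
    elif _ACC_FLOAT64 in accessions:
        dtype = "<f8"
    else:
        raise SpectrumParseError("binaryDataArray without a float-width cvParam")
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path) -> tuple[np.ndarray, np.ndarray]:
    """Read the first spectrum of an mzML file; returns (mz, intensity)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SpectrumParseError(f"not a well-formed mzML file: {exc}") from exc
    mz = intensity = None
    spectrum = next(tree.iter(f"{{{_NS}}}spectrum"), None)
    if spectrum is None:
        raise SpectrumParseError("mzML file contains no <spectrum> element")
    for bda in spectrum.iter(f"{{{_NS}}}binaryDataArray"):
        accessions = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")}
        if _ACC_MZ_ARRAY in accessions:
            mz = _decode_array(bda)
        elif _ACC_INTENSITY_ARRAY in accessions:
            intensity = _decode_array(bda)
    if mz is None or intensity is None:
        raise SpectrumParseError("spectrum lacks m/z or intensity array")
    if mz.shape != intensity.shape:
        raise SpectrumParseError("m/z and intensity arrays differ in length")
    return mz, intensity
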