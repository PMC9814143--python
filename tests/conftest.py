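"""Shared fixtures: noise-free simulation settings and a minimal mzML writer."""

from __future__ import annotations

import base64
import struct

import pytest

from oadlipid import SimulationConfig, default_registry, default_rules


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture()
def noise_free():
    """Simulation settings that reproduce reference spectra exactly."""
    return SimulationConfig(
        intensity_sigma=0.0, mz_sigma_ppm=0.0, noise_peak_lambda=0.0
    )


def _b64(values: list[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _spectrum_xml(index, prec, rt_min, mz, inten, ms_level=2, with_precursor=True):
    prec_block = ""
    if ms_level == 2 and with_precursor:
        prec_block = f"""
        <precursorList count="1"><precursor>
          <selectedIonList count="1"><selectedIon>
            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{prec}"/>
          </selectedIon></selectedIonList>
        </precursor></precursorList>"""
    rt_block = ""
    if rt_min is not None:
        rt_block = f"""
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min}" unitName="minute"/>
        </scan></scanList>"""
    return f"""
      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>{rt_block}{prec_block}
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
            <binary>{_b64(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{_b64(inten)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>"""


def write_minimal_mzml(path, spectra):
    """Write a tiny synthetic mzML file for reader tests.

    ``spectra``: iterable of dicts with keys mz, intensity, precursor_mz,
    rt_min, ms_level (default 2), with_precursor (default True).
    """
    body = "".join(
        _spectrum_xml(
            i, s.get("precursor_mz", 0.0), s.get("rt_min"), s["mz"],
            s["intensity"], s.get("ms_level", 2), s.get("with_precursor", True),
        )
        for i, s in enumerate(spectra)
    )
    xml = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1"><spectrumList count="{body.count('<spectrum ')}">{body}
  </spectrumList></run>
</mzML>"""
    with open(path, "w") as fh:
        fh.write(xml)
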