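import base64
import struct

import numpy as np
import pytest

from spectrotype.spectrum_io import PeakList, Spectrum, default_meta
from spectrotype.synthetic_data import NoiseModel


@pytest.fixture
def zero_noise():
    """Noise model with every stochastic term switched off (baseline kept)."""
    return NoiseModel(
        mz_jitter_sd=0.0,
        intensity_cv_technical=0.0,
        intensity_cv_biological=0.0,
        noise_sd=0.0,
    )


@pytest.fixture
def simple_spectrum():
    mz = np.linspace(3000.0, 15000.0, 1201)
    intensity = 0.2 + 0.8 * np.exp(-0.5 * ((mz - 8000.0) / 400.0) ** 2)
    return Spectrum(mz, intensity)


@pytest.fixture
def three_peak_list():
    return PeakList(
        np.array([5000.0, 8000.0, 11000.0]),
        np.array([0.5, 1.0, 0.25]),
        np.array([2.5, 4.0, 5.5]),
        default_meta(strain_id="S1", species="sp1", genus="G1"),
    )


def render_gaussians(mz_centers, heights, grid_step=0.5, sigma_of=None,
                     baseline_amp=0.05, mz_min=300.0, mz_max=20000.0):
    """Direct Gaussian-mixture renderer used as an independent fixture
    builder (bypasses PeakList invariants so sub-threshold peaks can be
    rendered)."""
    grid = np.arange(mz_min, mz_max + grid_step / 2, grid_step)
    y = baseline_amp * np.exp(-(grid - mz_min) / 3000.0)
    for m, h in zip(mz_centers, heights):
        sigma = (m / 2000.0) if sigma_of is None else sigma_of(m)
        y += h * np.exp(-0.5 * ((grid - m) / sigma) ** 2)
    return Spectrum(grid, y)


def minimal_mzml(mz, intensity) -> str:
    """Build a minimal single-spectrum profile mzML document."""

    def b64(arr):
        return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode()

    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="run1">
  <spectrumList count="1">
   <spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">
    <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{b64(mz)}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{b64(intensity)}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
  </spectrumList>
 </run>
</mzML>"""
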