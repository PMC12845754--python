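"""Shared fixtures: small synthetic datasets and a minimal EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from aesmbe.data import segment_run
from aesmbe.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Desk-scale study conditions: 2 subjects, 16 channels, 30 s runs."""
    return SyntheticConfig(
        n_subjects=2, n_channels=16, run_duration_s=30.0, snr=8.0, seed=11
    )


@pytest.fixture(scope="session")
def small_runs(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_windows(small_runs):
    return [w for r in small_runs for w in segment_run(r)]


def write_minimal_edf(path, data: np.ndarray, fs: int) -> None:
    """Write a bare-bones single-record EDF file (int16 samples).

    Synthetic fixture only — enough structure for standard EDF readers:
    one data record of duration n_samples/fs seconds per signal.
    """
    data = np.asarray(data, dtype=np.float64)
    n_sig, n_samp = data.shape
    phys_min, phys_max = -200.0, 200.0
    dig_min, dig_max = -32768, 32767
    duration = n_samp / fs

    def pad(text, width):
        return text[:width].ljust(width).encode("ascii")

    header = b""
    header += pad("0", 8)  # version
    header += pad("X X X X", 80)  # patient id
    header += pad("Startdate 01-JAN-2026 X X X", 80)  # recording id
    header += pad("01.01.26", 8)
    header += pad("00.00.00", 8)
    header += pad(str(256 * (1 + n_sig)), 8)  # header bytes
    header += pad("", 44)  # reserved
    header += pad("1", 8)  # number of data records
    header += pad(f"{duration:g}", 8)  # record duration (s)
    header += pad(str(n_sig), 4)

    fields = [
        ("EEG %03d" % i, 16) for i in range(n_sig)
    ]
    header += b"".join(pad(lbl, w) for lbl, w in fields)  # labels
    header += b"".join(pad("", 80) for _ in range(n_sig))  # transducer
    header += b"".join(pad("uV", 8) for _ in range(n_sig))  # dimension
    header += b"".join(pad(f"{phys_min:g}", 8) for _ in range(n_sig))
    header += b"".join(pad(f"{phys_max:g}", 8) for _ in range(n_sig))
    header += b"".join(pad(str(dig_min), 8) for _ in range(n_sig))
    header += b"".join(pad(str(dig_max), 8) for _ in range(n_sig))
    header += b"".join(pad("", 80) for _ in range(n_sig))  # prefiltering
    header += b"".join(pad(str(n_samp), 8) for _ in range(n_sig))
    header += b"".join(pad("", 32) for _ in range(n_sig))  # reserved

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for sig in digital:  # record layout: all samples of signal 0, then 1, ...
            fh.write(struct.pack(f"<{n_samp}h", *sig.tolist()))


@pytest.fixture()
def edf_file(tmp_path):
    """A 4-channel, 320-sample EDF fixture at 160 Hz with known content."""
    rng = np.random.default_rng(42)
    data = rng.uniform(-150, 150, size=(4, 320))
    path = tmp_path / "S001R01.edf"
    write_minimal_edf(path, data, fs=160)
    return path, data
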