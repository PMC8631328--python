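from __future__ import annotations

import numpy as np
import pytest

from fatiguewave.preprocess import EEGRecording
from fatiguewave.synthetic import CohortSpec, OddballSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort_spec():
    """A 3-subject, 24-second cohort: fast, but exercises the full chain."""
    return CohortSpec(n_subjects=3, duration_s=24.0, seed=42)


@pytest.fixture
def oddball_spec():
    return OddballSpec(total_duration_s=60.0, seed=7)


@pytest.fixture
def noise_recording(rng):
    data = rng.standard_normal((4, 5000))
    return EEGRecording(data=data, fs=250.0, subject=0, session="Day1")


def write_minimal_edf(path, data_uv, fs, labels) -> None:
    """Synthetic EDF writer for fixtures (int16, 1-second records).

    Only what the reader needs: physical range ±3200 µV mapped onto the
    full 16-bit digital range, one record per second.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    ns, n = data_uv.shape
    spr = int(fs)
    if n % spr:
        raise ValueError("need a whole number of 1-s records")
    n_rec = n // spr
    pmin, pmax = -3200.0, 3200.0
    dmin, dmax = -32768, 32767

    def fld(vals, width):
        return b"".join(str(v).encode().ljust(width) for v in vals)

    hdr = b"0".ljust(8)
    hdr += b"X".ljust(80) + b"X".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (ns + 1)).encode().ljust(8)
    hdr += b" " * 44
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(ns).encode().ljust(4)
    hdr += fld(labels, 16)
    hdr += fld([""] * ns, 80)
    hdr += fld(["uV"] * ns, 8)
    hdr += fld([pmin] * ns, 8) + fld([pmax] * ns, 8)
    hdr += fld([dmin] * ns, 8) + fld([dmax] * ns, 8)
    hdr += fld([""] * ns, 80)
    hdr += fld([spr] * ns, 8)
    hdr += b" " * (32 * ns)

    dig = np.round(
        (data_uv - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(dig[c, r * spr : (r + 1) * spr].tobytes())
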