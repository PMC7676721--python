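"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by the most direct
route possible (explicit double loops, closed forms) and never call the
package's own vectorized implementations.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force entropy oracles (explicit embedding loops)

def apen_bruteforce(x, m=2, tol_frac=0.2):
    """Approximate entropy by direct double-loop counting, self-matches in."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = tol_frac * np.std(x)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            count = 0
            for tj in templates:
                if np.max(np.abs(ti - tj)) <= r:
                    count += 1
            total += np.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m=2, tol_frac=0.2):
    """Sample entropy by direct pair counting, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = tol_frac * np.std(x)

    def pairs(mm):
        templates = [x[i : i + mm] for i in range(n - m)]
        count = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    count += 1
        return count

    a, b = pairs(m + 1), pairs(m)
    if a == 0 or b == 0:
        return float("inf")
    return -np.log(a / b)


def one_nn_bruteforce(train_X, train_y, test_X):
    """1-nearest-neighbour (Euclidean) labels by explicit search."""
    out = []
    for x in np.atleast_2d(test_X):
        d = np.sqrt(np.sum((np.asarray(train_X) - x) ** 2, axis=1))
        out.append(train_y[int(np.argmin(d))])
    return np.array(out)


# ---------------------------------------------------------------------------
# minimal EDF writer (test fixture generator; format per the EDF spec)

def write_edf(path, data, fs):
    """Write (n_channels, n_samples) float data as a minimal EDF file.

    One-second data records, int16 digital range, physical range chosen to
    cover the data.  Enough of the format for readers to recover channel
    count, sampling rate and (approximate) signal values.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    spr = int(fs)  # samples per 1 s record
    if n_samp % spr:
        raise ValueError("test EDF writer needs a whole number of 1 s records")
    n_rec = n_samp // spr

    pmax = max(1.0, float(np.max(np.abs(data)))) * 1.001
    dmin, dmax = -32768, 32767

    def pad(s, width):
        s = str(s)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad("synthetic test subject", 80),
        pad("synthetic test recording", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(256 * (n_ch + 1), 8),
        pad("", 44),
        pad(n_rec, 8),
        pad(1, 8),
        pad(n_ch, 4),
    ])
    header += b"".join(pad(f"EEG ch{c + 1}", 16) for c in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))
    header += b"".join(pad("uV", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{-pmax:.3f}"[:8], 8) for _ in range(n_ch))
    header += b"".join(pad(f"{pmax:.3f}"[:8], 8) for _ in range(n_ch))
    header += b"".join(pad(dmin, 8) for _ in range(n_ch))
    header += b"".join(pad(dmax, 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))
    header += b"".join(pad(spr, 8) for _ in range(n_ch))
    header += b"".join(pad("", 32) for _ in range(n_ch))

    scale = (dmax - dmin) / (2 * pmax)
    digital = np.round((data + pmax) * scale + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            for c in range(n_ch):
                fh.write(struct.pack(f"<{spr}h", *digital[c, rec * spr : (rec + 1) * spr]))
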