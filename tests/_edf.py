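"""Minimal EDF writer used only to exercise the package's EDF reader in
tests (the package itself writes delimited matrices).  Implements the plain
EDF spec: 256-byte fixed header, 256 bytes per signal header, int16 little-
endian samples, one data record per second."""

from __future__ import annotations

import numpy as np


def write_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    n_ch, n_samp = data.shape
    spr = int(round(fs))  # samples per 1-second record
    n_rec = n_samp // spr
    data = data[:, : n_rec * spr]

    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    scaled = np.clip(data, phys_min, phys_max)
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((scaled - phys_min) * gain + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("synthetic test recording", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(lbl, 16) for lbl in labels),
        b"".join(pad("synthetic", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(str(phys_min), 8) for _ in labels),
        b"".join(pad(str(phys_max), 8) for _ in labels),
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(spr), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr:(r + 1) * spr].tobytes())
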