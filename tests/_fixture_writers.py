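"""Synthetic test-fixture writers for the EDF and BrainVision readers.

These minimal writers exist only so the test suite can generate small
recordings on the fly (the deliverable contains no binary files); they
are not part of the package API and support just enough of each format
for round-trip testing through the MNE readers.
"""

from pathlib import Path

import numpy as np


def write_edf(path, data_uv, sfreq, ch_names):
    """Write a minimal EDF file (int16, physical units microvolts)."""
    path = Path(path)
    data_uv = np.asarray(data_uv, float)
    n_ch, n_samp = data_uv.shape
    record_s = 1.0
    spr = int(round(sfreq * record_s))
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "fixture length must be whole seconds"
    pmin, pmax = -500.0, 500.0
    dmin, dmax = -32768, 32767

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2020 X X X", 80),
        f("01.01.20", 8), f("00.00.00", 8), f(256 * (1 + n_ch), 8),
        f("", 44), f(n_rec, 8), f("%g" % record_s, 8), f(n_ch, 4),
    ])
    per = [
        b"".join(f(nm, 16) for nm in ch_names),
        b"".join(f("AgAgCl electrode", 80) for _ in ch_names),
        b"".join(f("uV", 8) for _ in ch_names),
        b"".join(f("%g" % pmin, 8) for _ in ch_names),
        b"".join(f("%g" % pmax, 8) for _ in ch_names),
        b"".join(f(dmin, 8) for _ in ch_names),
        b"".join(f(dmax, 8) for _ in ch_names),
        b"".join(f("", 80) for _ in ch_names),
        b"".join(f(spr, 8) for _ in ch_names),
        b"".join(f("", 32) for _ in ch_names),
    ]
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data_uv - pmin) * scale + dmin),
                      dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for block in per:
            fh.write(block)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def write_brainvision(basepath, data_uv, sfreq, ch_names):
    """Write a minimal BrainVision triple (.vhdr/.vmrk/.eeg, float32)."""
    base = Path(basepath)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    data_uv = np.asarray(data_uv, np.float32)
    n_ch = data_uv.shape[0]
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / sfreq:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, nm in enumerate(ch_names, start=1):
        lines.append(f"Ch{i}={nm},,1,uV")
    vhdr.write_text("\n".join(lines) + "\n")
    vmrk.write_text("\n".join([
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]) + "\n")
    data_uv.T.astype("<f4").tofile(eeg)
    return vhdr
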