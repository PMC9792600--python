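"""Programmatic writer for tiny synthetic EDF(+) files used as test input.

EDF headers are fixed-width ASCII, so minimal valid (and deliberately
corrupt) files can be forged directly.  Signals are sine waves; annotations
are written as an 'EDF Annotations' channel with standard TAL encoding.
"""

import numpy as np


def _field(value, width):
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} wider than {width}")
    return s.ljust(width).encode("ascii")


def write_minimal_edf(path, n_channels=2, fs=100, seconds=2,
                      annotations=None, declared_channels=None):
    """Write a tiny EDF file.

    ``annotations`` is a list of (onset_seconds, description) or None for a
    plain EDF without an annotation track.  ``declared_channels`` forges a
    corrupt header claiming a different signal count than is present.
    """
    n_records = seconds
    has_annot = annotations is not None
    ns_actual = n_channels + (1 if has_annot else 0)
    ns_declared = declared_channels if declared_channels is not None \
        else ns_actual
    annot_samples = 60                      # 120 bytes of TAL per record
    header_bytes = 256 * (1 + ns_actual)

    hdr = b""
    hdr += _field("0", 8)
    hdr += _field("X X X X", 80)
    hdr += _field("Startdate 01-JAN-2020 X X X", 80)
    hdr += _field("01.01.20", 8)
    hdr += _field("00.00.00", 8)
    hdr += _field(header_bytes, 8)
    hdr += _field("EDF+C" if has_annot else "", 44)
    hdr += _field(n_records, 8)
    hdr += _field(1, 8)                     # one second per record
    hdr += _field(ns_declared, 4)

    labels = [f"EEG ch{i}" for i in range(n_channels)]
    if has_annot:
        labels.append("EDF Annotations")
    spr = [fs] * n_channels + ([annot_samples] if has_annot else [])

    def per_signal(values, width):
        return b"".join(_field(v, width) for v in values)

    hdr += per_signal(labels, 16)
    hdr += per_signal([""] * ns_actual, 80)            # transducer
    hdr += per_signal(["uV"] * n_channels
                      + ([""] if has_annot else []), 8)
    hdr += per_signal([-100] * n_channels + ([-1] if has_annot else []), 8)
    hdr += per_signal([100] * n_channels + ([1] if has_annot else []), 8)
    hdr += per_signal([-32768] * ns_actual, 8)
    hdr += per_signal([32767] * ns_actual, 8)
    hdr += per_signal([""] * ns_actual, 80)            # prefiltering
    hdr += per_signal(spr, 8)
    hdr += per_signal([""] * ns_actual, 32)

    t = np.arange(fs) / fs
    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            for ch in range(n_channels):
                x = 50 * np.sin(2 * np.pi * (10 + ch) * (t + rec))
                digital = np.round(x / 100 * 32767).astype("<i2")
                fh.write(digital.tobytes())
            if has_annot:
                tal = f"+{rec}\x14\x14\x00".encode()
                for onset, desc in annotations:
                    if rec <= onset < rec + 1:
                        tal += f"+{onset}\x14{desc}\x14\x00".encode()
                tal = tal.ljust(2 * annot_samples, b"\x00")
                fh.write(tal[:2 * annot_samples])
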