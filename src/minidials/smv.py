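"""SMV image reading and writing.

SMV is the simple detector format used here for rotation images: a 512-byte
ASCII header of ``KEY=value;`` pairs wrapped in braces, padded with spaces,
followed by the raw pixel block (unsigned 16-bit, little-endian, slow axis
major).  One file per frame.
"""

from __future__ import annotations

import numpy as np

HEADER_BYTES = 512


def write_smv(path, data, header):
    """Write one SMV frame.

    ``data`` is a (n_slow, n_fast) array; values are clipped to uint16.
    ``header`` supplies DISTANCE, WAVELENGTH, OSC_START, OSC_RANGE,
    PIXEL_SIZE, BEAM_CENTER_X, BEAM_CENTER_Y (mm / deg, as floats).
    """
    data = np.asarray(data)
    n_slow, n_fast = data.shape
    fields = {
        "HEADER_BYTES": HEADER_BYTES,
        "DIM": 2,
        "BYTE_ORDER": "little_endian",
        "TYPE": "unsigned_short",
        "SIZE1": n_fast,
        "SIZE2": n_slow,
        "PIXEL_SIZE": header["PIXEL_SIZE"],
        "DISTANCE": header["DISTANCE"],
        "WAVELENGTH": header["WAVELENGTH"],
        "OSC_START": header["OSC_START"],
        "OSC_RANGE": header["OSC_RANGE"],
        "BEAM_CENTER_X": header["BEAM_CENTER_X"],
        "BEAM_CENTER_Y": header["BEAM_CENTER_Y"],
    }
    lines = ["{"] + [f"{k}={v};" for k, v in fields.items()] + ["}"]
    text = "\n".join(lines) + "\n"
    raw = text.encode("ascii")
    if len(raw) > HEADER_BYTES:
        raise ValueError("SMV header too long")
    raw = raw + b" " * (HEADER_BYTES - len(raw))
    pixels = np.clip(np.rint(data), 0, 65535).astype("<u2")
    with open(path, "wb") as fh:
        fh.write(raw)
        fh.write(pixels.tobytes())


def read_smv(path):
    """Read one SMV frame -> (data (n_slow, n_fast) uint16 array, header dict)."""
    with open(path, "rb") as fh:
        raw = fh.read(HEADER_BYTES)
        text = raw.decode("ascii", errors="replace")
        header = {}
        for line in text.splitlines():
            line = line.strip().strip("{}")
            if "=" in line:
                key, _, val = line.partition("=")
                header[key.strip()] = val.rstrip(";").strip()
        n_fast = int(header["SIZE1"])
        n_slow = int(header["SIZE2"])
        body = fh.read(2 * n_fast * n_slow)
    data = np.frombuffer(body, dtype="<u2").reshape(n_slow, n_fast)
    return data.copy(), header


def read_stack(paths):
    """Read a sorted list of SMV files -> (n_frames, n_slow, n_fast) array."""
    frames = []
    header = None
    for p in paths:
        data, hdr = read_smv(p)
        frames.append(data)
        if header is None:
            header = hdr
    return np.stack(frames), header
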