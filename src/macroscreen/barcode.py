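"""Minimal fixed-width 1-D barcode symbology for plate labels.

Both ends of the barcode path live in this package (the synthetic plate
renderer writes labels, the ingest stage reads them back), so the
symbology is a simple self-describing binary code rather than a commercial
standard: every plate label occupies a fixed number of equal-width modules,
which lets the decoder locate module centers from the registration-mark
transform alone.

Layout (one bit per module, 1 = black bar)::

    START(8) | LEN(8) | PAYLOAD(8 * capacity) | CHECKSUM(8) | STOP(8)

LEN is the payload length in characters, payload bytes are ASCII
(zero-padded to ``capacity``), and CHECKSUM is the byte sum of LEN and the
padded payload modulo 256.  START and STOP are asymmetric so a reversed
read cannot masquerade as a valid label.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CAPACITY", "n_modules", "encode", "decode_bits"]

START = np.array([1, 0, 1, 1, 0, 1, 1, 0], dtype=np.uint8)
STOP = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=np.uint8)

#: maximum payload length in characters
CAPACITY = 10


def n_modules(capacity: int = CAPACITY) -> int:
    """Total module count of an encoded label."""
    return 8 + 8 + 8 * capacity + 8 + 8


def _byte_bits(value: int) -> np.ndarray:
    return np.array([(value >> (7 - i)) & 1 for i in range(8)], dtype=np.uint8)


def encode(payload: str, capacity: int = CAPACITY) -> np.ndarray:
    """Encode an ASCII payload into a module bit array.

    Raises
    ------
    ValueError
        If the payload is empty, too long, or not ASCII.
    """
    if not payload:
        raise ValueError("barcode payload must be nonempty")
    try:
        raw = payload.encode("ascii")
    except UnicodeEncodeError as exc:
        raise ValueError(f"barcode payload must be ASCII: {payload!r}") from exc
    if len(raw) > capacity:
        raise ValueError(f"payload {payload!r} exceeds capacity {capacity}")
    padded = raw + b"\x00" * (capacity - len(raw))
    body = [len(raw), *padded]
    checksum = sum(body) % 256
    bits = np.concatenate(
        [START] + [_byte_bits(b) for b in body] + [_byte_bits(checksum), STOP]
    )
    assert bits.size == n_modules(capacity)
    return bits


def decode_bits(bits: np.ndarray, capacity: int = CAPACITY) -> str | None:
    """Decode a module bit array back to its payload.

    Returns ``None`` when the framing, checksum or length is invalid —
    callers treat that as an unreadable barcode, never an exception.
    """
    bits = np.asarray(bits).astype(np.uint8)
    if bits.size != n_modules(capacity):
        return None
    if not (np.array_equal(bits[:8], START) and np.array_equal(bits[-8:], STOP)):
        return None
    body_bits = bits[8:-16].reshape(-1, 8)
    weights = 1 << np.arange(7, -1, -1)
    body = body_bits @ weights
    checksum = int(bits[-16:-8] @ weights)
    if int(body.sum()) % 256 != checksum:
        return None
    length = int(body[0])
    if not 1 <= length <= capacity:
        return None
    raw = bytes(int(b) for b in body[1 : 1 + length])
    if any(b == 0 for b in raw):
        return None
    try:
        return raw.decode("ascii")
    except UnicodeDecodeError:
        return None
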