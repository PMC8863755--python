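"""AES-256 block cipher and CTR keystream, vectorized over blocks.

Self-contained implementation of the Advanced Encryption Standard with
256-bit keys (FIPS-197). State is held as a ``(n_blocks, 16)`` uint8
array in column-major (AES) order, and every round transformation —
SubBytes via table lookup, ShiftRows via fixed index permutation,
MixColumns via GF(2^8) xtime tables, AddRoundKey via XOR — is applied to
all blocks at once, which makes CTR-mode encryption of megabyte-scale
payloads practical in pure numpy.

Only what the encrypted export container needs is exposed: the key
schedule, single-block encryption (for the known-answer self-test) and
the CTR keystream. Authentication lives in :mod:`phonelog.secure`
(HMAC-SHA256, encrypt-then-MAC).
"""

from __future__ import annotations

import numpy as np

__all__ = ["aes256_expand_key", "aes256_encrypt_blocks", "ctr_keystream", "ctr_xor"]

_SBOX = np.array(
    [
        0x63, 0x7C, 0x77, 0x7B, 0xF2, 0x6B, 0x6F, 0xC5, 0x30, 0x01, 0x67, 0x2B,
        0xFE, 0xD7, 0xAB, 0x76, 0xCA, 0x82, 0xC9, 0x7D, 0xFA, 0x59, 0x47, 0xF0,
        0xAD, 0xD4, 0xA2, 0xAF, 0x9C, 0xA4, 0x72, 0xC0, 0xB7, 0xFD, 0x93, 0x26,
        0x36, 0x3F, 0xF7, 0xCC, 0x34, 0xA5, 0xE5, 0xF1, 0x71, 0xD8, 0x31, 0x15,
        0x04, 0xC7, 0x23, 0xC3, 0x18, 0x96, 0x05, 0x9A, 0x07, 0x12, 0x80, 0xE2,
        0xEB, 0x27, 0xB2, 0x75, 0x09, 0x83, 0x2C, 0x1A, 0x1B, 0x6E, 0x5A, 0xA0,
        0x52, 0x3B, 0xD6, 0xB3, 0x29, 0xE3, 0x2F, 0x84, 0x53, 0xD1, 0x00, 0xED,
        0x20, 0xFC, 0xB1, 0x5B, 0x6A, 0xCB, 0xBE, 0x39, 0x4A, 0x4C, 0x58, 0xCF,
        0xD0, 0xEF, 0xAA, 0xFB, 0x43, 0x4D, 0x33, 0x85, 0x45, 0xF9, 0x02, 0x7F,
        0x50, 0x3C, 0x9F, 0xA8, 0x51, 0xA3, 0x40, 0x8F, 0x92, 0x9D, 0x38, 0xF5,
        0xBC, 0xB6, 0xDA, 0x21, 0x10, 0xFF, 0xF3, 0xD2, 0xCD, 0x0C, 0x13, 0xEC,
        0x5F, 0x97, 0x44, 0x17, 0xC4, 0xA7, 0x7E, 0x3D, 0x64, 0x5D, 0x19, 0x73,
        0x60, 0x81, 0x4F, 0xDC, 0x22, 0x2A, 0x90, 0x88, 0x46, 0xEE, 0xB8, 0x14,
        0xDE, 0x5E, 0x0B, 0xDB, 0xE0, 0x32, 0x3A, 0x0A, 0x49, 0x06, 0x24, 0x5C,
        0xC2, 0xD3, 0xAC, 0x62, 0x91, 0x95, 0xE4, 0x79, 0xE7, 0xC8, 0x37, 0x6D,
        0x8D, 0xD5, 0x4E, 0xA9, 0x6C, 0x56, 0xF4, 0xEA, 0x65, 0x7A, 0xAE, 0x08,
        0xBA, 0x78, 0x25, 0x2E, 0x1C, 0xA6, 0xB4, 0xC6, 0xE8, 0xDD, 0x74, 0x1F,
        0x4B, 0xBD, 0x8B, 0x8A, 0x70, 0x3E, 0xB5, 0x66, 0x48, 0x03, 0xF6, 0x0E,
        0x61, 0x35, 0x57, 0xB9, 0x86, 0xC1, 0x1D, 0x9E, 0xE1, 0xF8, 0x98, 0x11,
        0x69, 0xD9, 0x8E, 0x94, 0x9B, 0x1E, 0x87, 0xE9, 0xCE, 0x55, 0x28, 0xDF,
        0x8C, 0xA1, 0x89, 0x0D, 0xBF, 0xE6, 0x42, 0x68, 0x41, 0x99, 0x2D, 0x0F,
        0xB0, 0x54, 0xBB, 0x16,
    ],
    dtype=np.uint8,
)

# xtime table: multiplication by 2 in GF(2^8) mod x^8+x^4+x^3+x+1
_X2 = np.empty(256, dtype=np.uint8)
for _i in range(256):
    _v = _i << 1
    if _v & 0x100:
        _v ^= 0x11B
    _X2[_i] = _v
_X3 = _X2 ^ np.arange(256, dtype=np.uint8)

_RCON = (0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36, 0x6C)

# ShiftRows permutation on the 16-byte block laid out column-major:
# byte index = 4*col + row; row r rotates left by r columns.
_SHIFT_ROWS = np.array(
    [4 * ((c + r) % 4) + r for c in range(4) for r in range(4)], dtype=np.intp
)


def aes256_expand_key(key: bytes) -> np.ndarray:
    """Expand a 32-byte key into the 15 round keys, shape (15, 16) uint8."""
    if len(key) != 32:
        raise ValueError("AES-256 requires a 32-byte key")
    w = [np.frombuffer(key[i : i + 4], dtype=np.uint8).copy() for i in range(0, 32, 4)]
    for i in range(8, 60):
        temp = w[i - 1].copy()
        if i % 8 == 0:
            temp = np.roll(temp, -1)
            temp = _SBOX[temp]
            temp[0] ^= _RCON[i // 8 - 1]
        elif i % 8 == 4:
            temp = _SBOX[temp]
        w.append(w[i - 8] ^ temp)
    words = np.stack(w)  # (60, 4)
    return words.reshape(15, 16)


def _mix_columns(state: np.ndarray) -> np.ndarray:
    # state: (n, 16) column-major; each column is bytes [4c:4c+4]
    s = state.reshape(-1, 4, 4)  # (n, col, row)
    a0, a1, a2, a3 = s[:, :, 0], s[:, :, 1], s[:, :, 2], s[:, :, 3]
    out = np.empty_like(s)
    out[:, :, 0] = _X2[a0] ^ _X3[a1] ^ a2 ^ a3
    out[:, :, 1] = a0 ^ _X2[a1] ^ _X3[a2] ^ a3
    out[:, :, 2] = a0 ^ a1 ^ _X2[a2] ^ _X3[a3]
    out[:, :, 3] = _X3[a0] ^ a1 ^ a2 ^ _X2[a3]
    return out.reshape(-1, 16)


def aes256_encrypt_blocks(blocks: np.ndarray, round_keys: np.ndarray) -> np.ndarray:
    """Encrypt ``(n, 16)`` uint8 plaintext blocks; returns ciphertext blocks."""
    state = blocks ^ round_keys[0]
    for r in range(1, 14):
        state = _SBOX[state]
        state = state[:, _SHIFT_ROWS]
        state = _mix_columns(state)
        state ^= round_keys[r]
    state = _SBOX[state]
    state = state[:, _SHIFT_ROWS]
    state ^= round_keys[14]
    return state


def ctr_keystream(key: bytes, nonce: bytes, n_bytes: int) -> np.ndarray:
    """CTR keystream: AES(counter blocks) for a 16-byte initial counter."""
    if len(nonce) != 16:
        raise ValueError("CTR nonce/counter must be 16 bytes")
    n_blocks = (n_bytes + 15) // 16
    ctr0 = int.from_bytes(nonce, "big")
    counters = (ctr0 + np.arange(n_blocks, dtype=object)) % (1 << 128)
    # materialize counter blocks as bytes
    blocks = np.empty((n_blocks, 16), dtype=np.uint8)
    for i, c in enumerate(counters):
        blocks[i] = np.frombuffer(int(c).to_bytes(16, "big"), dtype=np.uint8)
    rk = aes256_expand_key(key)
    ks = aes256_encrypt_blocks(blocks, rk)
    return ks.reshape(-1)[:n_bytes]


def ctr_xor(key: bytes, nonce: bytes, data: bytes) -> bytes:
    """Encrypt or decrypt (CTR is an involution) ``data`` under key/nonce."""
    ks = ctr_keystream(key, nonce, len(data))
    buf = np.frombuffer(data, dtype=np.uint8) ^ ks
    return buf.tobytes()
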