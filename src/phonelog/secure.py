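"""Secure export: consent-tap passwords and the AES-256 container.

Two pieces of the export path live here.

**Password generation from user-generated randomness.** Rather than ask
participants to invent a password, the logger harvests the UNIX-ms
timestamps of their consent-dialog taps — incidental, unpredictable
values — stores them in a random order, randomly queries one, and uses
it to seed a random character generator. The emitted password draws from
uppercase, lowercase, digits and symbols and is guaranteed to contain at
least one character of each class.

**Encrypted container.** Exports travel as a single password-protected
file. The container holds the canonical CSV table encrypted with
AES-256 in CTR mode, authenticated with HMAC-SHA256 (encrypt-then-MAC),
with independent keys derived from the password by PBKDF2-HMAC-SHA256.
A wrong password fails authentication cleanly — no partial plaintext is
ever released — and the cipher key length is 256 bits by construction.
"""

from __future__ import annotations

import hashlib
import hmac
import os
import random
import string
from dataclasses import dataclass

from ._aes import ctr_xor

__all__ = [
    "ConsentTapLog",
    "EncryptedExport",
    "CrashReport",
    "AuthenticationError",
    "ContainerFormatError",
    "PASSWORD_CHARSET",
    "generate_password",
    "encrypt_export",
    "decrypt_export",
    "parse_crash_report",
]

#: 26 + 26 + 10 + 12 = 74 characters; a variety of classes resists
#: brute-force search better than letters alone.
PASSWORD_SYMBOLS = "!@#$%^&*()-_"
PASSWORD_CHARSET = (
    string.ascii_uppercase + string.ascii_lowercase + string.digits + PASSWORD_SYMBOLS
)
_CLASSES = (
    string.ascii_uppercase,
    string.ascii_lowercase,
    string.digits,
    PASSWORD_SYMBOLS,
)

_MAGIC = b"PHONELOG-ENC\x01"
_KINDS = ("context", "continuous", "usage", "crash")
_PBKDF2_ITERS = 200_000


class AuthenticationError(Exception):
    """Wrong password or tampered container."""


class ContainerFormatError(Exception):
    """Bytes do not parse as an export container."""


@dataclass
class ConsentTapLog:
    """UNIX-ms timestamps of the participant's consent-dialog taps."""

    tap_timestamps_ms: list[int]

    def __post_init__(self) -> None:
        ts = self.tap_timestamps_ms
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("tap timestamps must be strictly increasing")


@dataclass
class EncryptedExport:
    """An opaque password-protected export plus its payload kind."""

    data: bytes
    payload_kind: str
    cipher: str = "AES"
    key_bits: int = 256


@dataclass(frozen=True)
class CrashReport:
    manufacturer: str
    model: str
    code_location: str
    timestamp_ms: int


def generate_password(
    taps: ConsentTapLog, length: int = 16, rng_seed: int | None = None
) -> str:
    """Derive a password from consent-tap timing.

    The tap list is shuffled, one element drawn at random, and that
    timestamp seeds the character generator. Deterministic given
    ``(taps, length, rng_seed)``; at least one character of each of the
    four classes is always present.
    """
    if not taps.tap_timestamps_ms:
        raise ValueError("consent tap log is empty; cannot generate a password")
    if length < 8:
        raise ValueError("password length must be at least 8")
    ambient = random.Random(rng_seed)
    shuffled = list(taps.tap_timestamps_ms)
    ambient.shuffle(shuffled)
    seed_value = shuffled[ambient.randrange(len(shuffled))]

    gen = random.Random(seed_value * 1_000_003 + length)
    # one from each class first, remainder from the full charset, then a
    # final shuffle by the same generator — coverage without bias spikes
    chars = [gen.choice(cls) for cls in _CLASSES]
    chars += [gen.choice(PASSWORD_CHARSET) for _ in range(length - len(chars))]
    gen.shuffle(chars)
    return "".join(chars[:length])


def _derive_keys(password: str, salt: bytes) -> tuple[bytes, bytes]:
    km = hashlib.pbkdf2_hmac("sha256", password.encode(), salt, _PBKDF2_ITERS, dklen=64)
    return km[:32], km[32:]


def encrypt_export(
    table_text: str, password: str, payload_kind: str = "continuous"
) -> EncryptedExport:
    """Wrap a CSV table in the password-protected container.

    An empty table is valid (a header-only export). Layout: magic, kind,
    16-byte salt, 16-byte CTR nonce, ciphertext, 32-byte HMAC-SHA256 tag
    over everything preceding it.
    """
    if not password:
        raise ValueError("password must be non-empty")
    if payload_kind not in _KINDS:
        raise ValueError(f"payload_kind must be one of {_KINDS}")
    salt = os.urandom(16)
    nonce = os.urandom(16)
    enc_key, mac_key = _derive_keys(password, salt)
    ciphertext = ctr_xor(enc_key, nonce, table_text.encode("utf-8"))
    body = _MAGIC + payload_kind.encode().ljust(10, b"\x00") + salt + nonce + ciphertext
    tag = hmac.new(mac_key, body, hashlib.sha256).digest()
    return EncryptedExport(body + tag, payload_kind)


def decrypt_export(container: EncryptedExport | bytes, password: str) -> tuple[str, str]:
    """Open a container; returns ``(table_text, payload_kind)``.

    Raises :class:`AuthenticationError` on a wrong password (before any
    plaintext is produced) and :class:`ContainerFormatError` on bytes
    that are not a container.
    """
    data = container.data if isinstance(container, EncryptedExport) else container
    if len(data) < len(_MAGIC) + 10 + 16 + 16 + 32 or not data.startswith(_MAGIC):
        raise ContainerFormatError("not a phonelog export container")
    off = len(_MAGIC)
    kind = data[off : off + 10].rstrip(b"\x00").decode()
    off += 10
    salt = data[off : off + 16]
    nonce = data[off + 16 : off + 32]
    off += 32
    body, tag = data[:-32], data[-32:]
    ciphertext = data[off:-32]
    if kind not in _KINDS:
        raise ContainerFormatError(f"unknown payload kind {kind!r}")
    enc_key, mac_key = _derive_keys(password, salt)
    expected = hmac.new(mac_key, body, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expected):
        raise AuthenticationError("wrong password or corrupted container")
    return ctr_xor(enc_key, nonce, ciphertext).decode("utf-8"), kind


def parse_crash_report(rows: list[list[str]]) -> tuple[list[CrashReport], list[str]]:
    """Parse crash-payload rows into :class:`CrashReport` records.

    Each row is ``[manufacturer, model, code_location, timestamp_ms]``.
    Malformed rows are skipped and reported as reasons.
    """
    reports: list[CrashReport] = []
    problems: list[str] = []
    for i, row in enumerate(rows):
        if len(row) != 4:
            problems.append(f"row {i}: expected 4 fields, got {len(row)}")
            continue
        manufacturer, model, loc, ts = (c.strip() for c in row)
        if not (manufacturer and model and loc):
            problems.append(f"row {i}: empty field")
            continue
        try:
            ts_ms = int(ts)
        except ValueError:
            problems.append(f"row {i}: missing or non-integer timestamp")
            continue
        reports.append(CrashReport(manufacturer, model, loc, ts_ms))
    return reports, problems
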