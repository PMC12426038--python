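"""Keyed pseudonym vault: deterministic reversible masking.

Pseudonyms are HMAC-SHA256 tokens of ``(category, normalized original)`` under
a user-held secret, so the same patient identifier maps to the same token
wherever it appears (referential consistency), tokens are stable across runs,
and nothing about the original is recoverable from the token alone.  Because a
keyed hash is one-way, reversal requires the vault: a bidirectional
pseudonym<->original store persisted encrypted under keys derived from the
same secret.

The store format is authenticated encryption built from the standard library:
two HKDF-style derived keys (encrypt / MAC), a deterministic SIV-style nonce
(HMAC of the plaintext), a SHA-256 counter keystream, and an
encrypt-then-MAC HMAC-SHA256 tag.  Opening with the wrong secret fails the
tag check and raises :class:`VaultLocked`.  Deterministic encryption keeps
whole pipeline runs byte-reproducible.

Besides pseudonyms, the vault can hold per-document *restore* entries
(original value + kind for suppressed or generalized leaves), which is what
makes an authorized trusted-party re-identification an exact inverse of
de-identification.  Identifiable data never lives outside this encrypted
store.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import os
import re
from dataclasses import dataclass, field
from typing import Any, Optional

from .errors import UnknownPseudonym, VaultLocked, VaultWriteFailure

_MAGIC = b"WDV1"
_TOKEN_RE = re.compile(r"PSN-[A-Z0-9]+-[0-9a-f]{16}")


def _derive(secret: bytes, purpose: bytes) -> bytes:
    return hmac.new(secret, b"wisedeid-vault:" + purpose, hashlib.sha256).digest()


def _keystream_xor(key: bytes, nonce: bytes, data: bytes) -> bytes:
    out = bytearray(len(data))
    for block in range(0, len(data), 32):
        counter = (block // 32).to_bytes(8, "big")
        pad = hashlib.sha256(key + nonce + counter).digest()
        chunk = data[block:block + 32]
        out[block:block + len(chunk)] = bytes(a ^ b for a, b in zip(chunk, pad))
    return bytes(out)


def _encrypt(secret: bytes, plaintext: bytes) -> bytes:
    enc_key = _derive(secret, b"enc")
    mac_key = _derive(secret, b"mac")
    nonce = hmac.new(_derive(secret, b"siv"), plaintext, hashlib.sha256).digest()[:16]
    ct = _keystream_xor(enc_key, nonce, plaintext)
    tag = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    return _MAGIC + nonce + tag + ct


def _decrypt(secret: bytes, blob: bytes) -> bytes:
    if len(blob) < 4 + 16 + 32 or blob[:4] != _MAGIC:
        raise VaultLocked("not a vault file")
    nonce, tag, ct = blob[4:20], blob[20:52], blob[52:]
    mac_key = _derive(secret, b"mac")
    expect = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expect):
        raise VaultLocked("authentication failed: wrong key material")
    return _keystream_xor(_derive(secret, b"enc"), nonce, ct)


@dataclass
class PseudonymVault:
    """Bidirectional pseudonym store, unlocked by secret key material."""

    secret: Optional[bytes] = None
    forward: dict[str, str] = field(default_factory=dict)   # "cat|normalized" -> token
    reverse: dict[str, str] = field(default_factory=dict)   # token -> original
    restores: dict[str, list] = field(default_factory=dict)  # source_id -> [(path, value, kind)]
    contexts: dict[str, str] = field(default_factory=dict)   # source_id -> sharing context
    orders: dict[str, list] = field(default_factory=dict)    # source_id -> original path order

    # -- lifecycle ----------------------------------------------------------

    @classmethod
    def create(cls, secret: bytes) -> "PseudonymVault":
        if not secret:
            raise VaultLocked("empty key material")
        return cls(secret=secret)

    @classmethod
    def open(cls, path: str, secret: bytes) -> "PseudonymVault":
        with open(path, "rb") as fh:
            blob = base64.b64decode(fh.read())
        payload = json.loads(_decrypt(secret, blob).decode("utf-8"))
        return cls(secret=secret, forward=payload["forward"],
                   reverse=payload["reverse"],
                   restores=payload.get("restores", {}),
                   contexts=payload.get("contexts", {}),
                   orders=payload.get("orders", {}))

    @classmethod
    def open_or_create(cls, path: str, secret: bytes) -> "PseudonymVault":
        if path and os.path.exists(path):
            return cls.open(path, secret)
        return cls.create(secret)

    def save(self, path: str) -> None:
        self._require_unlocked()
        payload = json.dumps({"forward": self.forward, "reverse": self.reverse,
                              "restores": self.restores, "contexts": self.contexts,
                              "orders": self.orders},
                             sort_keys=True).encode("utf-8")
        try:
            with open(path, "wb") as fh:
                fh.write(base64.b64encode(_encrypt(self.secret, payload)))
        except OSError as exc:
            raise VaultWriteFailure(str(exc)) from exc

    def _require_unlocked(self) -> None:
        if not self.secret:
            raise VaultLocked("vault has no key material")

    # -- pseudonyms ---------------------------------------------------------

    def token(self, category: str, original: str) -> str:
        """Deterministic pseudonym for (category, original); records both directions."""
        self._require_unlocked()
        normalized = str(original).strip()
        key = f"{category}|{normalized}"
        if key in self.forward:
            return self.forward[key]
        digest = hmac.new(_derive(self.secret, b"token"),
                          key.encode("utf-8"), hashlib.sha256).hexdigest()[:16]
        cat_code = re.sub(r"[^A-Z0-9]", "", category.upper())[:8] or "X"
        tok = f"PSN-{cat_code}-{digest}"
        self.forward[key] = tok
        self.reverse[tok] = normalized
        return tok

    def original(self, pseudonym: str) -> str:
        self._require_unlocked()
        try:
            return self.reverse[pseudonym]
        except KeyError:
            raise UnknownPseudonym(pseudonym) from None

    @staticmethod
    def find_tokens(text: str) -> list[str]:
        return _TOKEN_RE.findall(text)

    # -- restores (exact reversal of suppression/generalization) ------------

    def record_restore(self, source_id: str, path: str, value: Any, kind: str) -> None:
        self._require_unlocked()
        self.restores.setdefault(source_id, []).append([path, value, kind])

    def restores_for(self, source_id: str) -> list:
        return self.restores.get(source_id, [])

    def record_context(self, source_id: str, context: str) -> None:
        self.contexts[source_id] = context

    def record_order(self, source_id: str, paths: list[str]) -> None:
        """Original leaf order (structure only, no values) for exact rebuilds."""
        self.orders[source_id] = list(paths)
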