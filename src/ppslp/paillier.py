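"""Paillier additively homomorphic cryptosystem.

Plaintexts live in Z_n, ciphertexts in the multiplicative group mod n².
Multiplying ciphertexts adds plaintexts; raising a ciphertext to an integer
power multiplies its plaintext by that integer.  These two identities are
the arithmetic substrate for every secure protocol in this package:

    D(E(m1) * E(m2) mod n²) = (m1 + m2) mod n
    D(E(m)^k     mod n²)    = k * m     mod n

Encryption is ``c = g^m * r^n mod n²`` with a fresh blinding residue ``r``
coprime to ``n``, so equal plaintexts yield unequal ciphertexts
(semantic security under fixed keys).

All arithmetic uses Python's arbitrary-precision integers; primality
testing is delegated to :func:`sympy.isprime`.
"""

from __future__ import annotations

import json
import math
import os
import random
from dataclasses import dataclass, field
from functools import lru_cache

import sympy

__all__ = [
    "PublicKey",
    "PrivateKey",
    "Ciphertext",
    "OpLedger",
    "keygen",
    "encrypt",
    "decrypt",
    "hom_add",
    "hom_scalar",
    "save_keys",
    "load_public_key",
    "load_private_key",
]

_PRIME_ATTEMPT_BUDGET = 50_000


class KeygenError(RuntimeError):
    """Prime search exhausted its attempt budget."""


class MalformedCiphertext(ValueError):
    """Ciphertext residue shares a factor with n and cannot be decrypted."""


class KeyMismatch(ValueError):
    """Operands were encrypted under different public keys."""


@dataclass
class OpLedger:
    """Tally of ciphertext-level operations, for cost accounting.

    EXP counts modular exponentiations of a ciphertext, MUL counts
    multiplications mod n², DIV counts the modular inversion performed
    once per decryption.
    """

    EXP: int = 0
    MUL: int = 0
    DIV: int = 0

    def tick(self, op: str, k: int = 1) -> None:
        setattr(self, op, getattr(self, op) + k)

    def as_dict(self) -> dict[str, int]:
        return {"EXP": self.EXP, "MUL": self.MUL, "DIV": self.DIV}

    def __add__(self, other: "OpLedger") -> "OpLedger":
        return OpLedger(self.EXP + other.EXP, self.MUL + other.MUL, self.DIV + other.DIV)


@dataclass(frozen=True)
class PublicKey:
    """Public key (n, g); n = p*q for secret primes, g generates plaintexts."""

    n: int
    g: int
    n_sq: int = field(repr=False, default=0)

    def __post_init__(self) -> None:
        if self.n_sq == 0:
            object.__setattr__(self, "n_sq", self.n * self.n)

    @property
    def key_id(self) -> str:
        return format(self.n % (1 << 64), "016x")


@dataclass(frozen=True)
class PrivateKey:
    """Private key (λ, μ); the primes are retained for tests and key files."""

    lam: int
    mu: int
    p: int
    q: int


@dataclass(frozen=True)
class Ciphertext:
    """A residue in [1, n²) tagged with the id of the encrypting key."""

    value: int
    key_id: str


def _L(x: int, n: int) -> int:
    # exact by construction: x ≡ 1 (mod n) for every valid argument
    return (x - 1) // n


def _random_prime(bits: int, rng: random.Random) -> int:
    for _ in range(_PRIME_ATTEMPT_BUDGET):
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        if sympy.isprime(cand):
            return cand
    raise KeygenError(f"no {bits}-bit prime found in {_PRIME_ATTEMPT_BUDGET} attempts")


def keygen(
    bits: int = 256,
    seed: int | None = None,
    random_g: bool = False,
) -> tuple[PublicKey, PrivateKey]:
    """Generate a Paillier key pair with ``bits``-bit primes.

    Parameters
    ----------
    bits
        Bit length of each prime.  256 is comfortable for testing;
        production deployments should use >= 1024.
    seed
        Optional RNG seed; the same seed always yields the same key pair.
    random_g
        When True, draw g uniformly from the valid generators instead of
        using the default ``g = n + 1`` (always valid, and cheapest).
    """
    if bits < 128:
        raise ValueError("bits must be >= 128 even for testing (>= 1024 for production)")
    rng = random.Random(seed) if seed is not None else random.SystemRandom()
    while True:
        p = _random_prime(bits, rng)
        q = _random_prime(bits, rng)
        if p == q:
            continue
        n = p * q
        if math.gcd(n, (p - 1) * (q - 1)) != 1:
            continue
        break
    lam = math.lcm(p - 1, q - 1)
    n_sq = n * n
    if random_g:
        while True:
            g = rng.randrange(2, n_sq)
            if math.gcd(g, n_sq) != 1:
                continue
            u = _L(pow(g, lam, n_sq), n)
            if math.gcd(u, n) == 1:
                break
    else:
        g = n + 1
    mu = pow(_L(pow(g, lam, n_sq), n), -1, n)
    return PublicKey(n=n, g=g), PrivateKey(lam=lam, mu=mu, p=p, q=q)


def _sample_blinding(n: int, rng: random.Random) -> int:
    while True:
        r = rng.randrange(1, n)
        if math.gcd(r, n) == 1:
            return r


def encrypt(
    pk: PublicKey,
    m: int,
    r: int | None = None,
    rng: random.Random | None = None,
    ledger: OpLedger | None = None,
) -> Ciphertext:
    """Encrypt a residue m in [0, n) as ``g^m * r^n mod n²``."""
    if not 0 <= m < pk.n:
        raise ValueError(f"plaintext {m} outside [0, n)")
    if r is None:
        r = _sample_blinding(pk.n, rng if rng is not None else random.SystemRandom())
    else:
        if not 0 < r < pk.n:
            raise ValueError("blinding r must lie in (0, n)")
        if math.gcd(r, pk.n) != 1:
            raise ValueError("blinding r must be coprime to n")
    if pk.g == pk.n + 1:
        # (n+1)^m = 1 + m*n (mod n²): one multiplication instead of a pow
        gm = (1 + m * pk.n) % pk.n_sq
    else:
        gm = pow(pk.g, m, pk.n_sq)
    c = (gm * pow(r, pk.n, pk.n_sq)) % pk.n_sq
    if ledger is not None:
        ledger.tick("EXP", 2)
        ledger.tick("MUL", 1)
    return Ciphertext(value=c, key_id=pk.key_id)


@lru_cache(maxsize=8)
def _crt_params(sk: PrivateKey, pk: PublicKey) -> tuple[int, int, int, int, int]:
    """Precomputed constants for prime-wise decryption.

    Decrypting mod p² and q² separately and recombining by the Chinese
    remainder theorem gives the same plaintext as the textbook formula
    (the plaintext is unique) at a fraction of the exponentiation cost.
    """
    p, q = sk.p, sk.q
    p_sq, q_sq = p * p, q * q
    hp = pow((pow(pk.g, p - 1, p_sq) - 1) // p, -1, p)
    hq = pow((pow(pk.g, q - 1, q_sq) - 1) // q, -1, q)
    q_inv_p = pow(q, -1, p)
    return p_sq, q_sq, hp, hq, q_inv_p


def decrypt(
    sk: PrivateKey,
    pk: PublicKey,
    c: Ciphertext,
    ledger: OpLedger | None = None,
) -> int:
    """Recover the plaintext residue: ``L(c^λ mod n²) * μ mod n``.

    When the private key carries the primes, the equivalent prime-wise
    CRT evaluation is used for speed; otherwise the direct formula runs.
    """
    if c.key_id != pk.key_id:
        raise KeyMismatch("ciphertext was not produced under this public key")
    if not 1 <= c.value < pk.n_sq:
        raise MalformedCiphertext("ciphertext residue outside [1, n²)")
    if math.gcd(c.value, pk.n) != 1:
        raise MalformedCiphertext("ciphertext residue shares a factor with n")
    if sk.p and sk.q and sk.p * sk.q == pk.n:
        p_sq, q_sq, hp, hq, q_inv_p = _crt_params(sk, pk)
        mp = ((pow(c.value, sk.p - 1, p_sq) - 1) // sk.p) * hp % sk.p
        mq = ((pow(c.value, sk.q - 1, q_sq) - 1) // sk.q) * hq % sk.q
        m = (mq + sk.q * ((q_inv_p * (mp - mq)) % sk.p)) % pk.n
    else:
        m = (_L(pow(c.value, sk.lam, pk.n_sq), pk.n) * sk.mu) % pk.n
    if ledger is not None:
        ledger.tick("EXP", 1)
        ledger.tick("DIV", 1)
    return m


def hom_add(
    pk: PublicKey,
    c1: Ciphertext,
    c2: Ciphertext,
    ledger: OpLedger | None = None,
) -> Ciphertext:
    """Ciphertext of (m1 + m2) mod n, by multiplying ciphertexts mod n²."""
    if c1.key_id != c2.key_id or c1.key_id != pk.key_id:
        raise KeyMismatch("hom_add operands must share one public key")
    if ledger is not None:
        ledger.tick("MUL", 1)
    return Ciphertext(value=(c1.value * c2.value) % pk.n_sq, key_id=pk.key_id)


def hom_scalar(
    pk: PublicKey,
    c: Ciphertext,
    k: int,
    ledger: OpLedger | None = None,
) -> Ciphertext:
    """Ciphertext of k*m mod n, by raising the ciphertext to the k-th power.

    k must be a non-negative residue; callers encode a negative scalar -k
    as the exponent n - k (additive inverse in the plaintext group).
    """
    if c.key_id != pk.key_id:
        raise KeyMismatch("ciphertext was not produced under this public key")
    if not 0 <= k < pk.n:
        raise ValueError("scalar exponent must lie in [0, n); map -k to n-k first")
    if ledger is not None:
        ledger.tick("EXP", 1)
    return Ciphertext(value=pow(c.value, k, pk.n_sq), key_id=pk.key_id)


# ---------------------------------------------------------------------------
# key files: JSON with hex-encoded big integers


def save_keys(pk: PublicKey, sk: PrivateKey, pub_path: str, priv_path: str) -> None:
    """Write the public key world-readable and the private key mode 0600."""
    with open(pub_path, "w") as f:
        json.dump({"n": hex(pk.n), "g": hex(pk.g)}, f)
    fd = os.open(priv_path, os.O_WRONLY | os.O_CREAT | os.O_TRUNC, 0o600)
    with os.fdopen(fd, "w") as f:
        json.dump(
            {"lambda": hex(sk.lam), "mu": hex(sk.mu), "p": hex(sk.p), "q": hex(sk.q)},
            f,
        )


def load_public_key(path: str) -> PublicKey:
    with open(path) as f:
        d = json.load(f)
    return PublicKey(n=int(d["n"], 16), g=int(d["g"], 16))


def load_private_key(path: str) -> PrivateKey:
    with open(path) as f:
        d = json.load(f)
    return PrivateKey(
        lam=int(d["lambda"], 16), mu=int(d["mu"], 16), p=int(d["p"], 16), q=int(d["q"], 16)
    )
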