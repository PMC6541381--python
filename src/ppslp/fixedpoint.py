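"""Signed fixed-point encoding of real values into the Paillier plaintext space.

Real-valued attributes and weights are scaled by a power of ten, rounded,
and mapped into Z_n with negatives represented as n - |value| — the
standard two's-complement-style convention for additively homomorphic
plaintexts.  The symmetric midpoint n/2 splits the ring: residues at or
below it decode as non-negative, residues above as negative.  Encoding
therefore requires |x| * 10^scale_exp < n/2, which the guard enforces.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EncodedScalar", "encode", "decode", "signed_value", "FixedPointOverflow"]

DEFAULT_SCALE_EXP = 4


class FixedPointOverflow(OverflowError):
    """Scaled magnitude reached n/2, where the sign becomes ambiguous."""


@dataclass(frozen=True)
class EncodedScalar:
    """A signed fixed-point value as a residue in Z_n.

    ``residue`` is the ring element, ``scale_exp`` the power-of-ten scale
    (the represented value is signed(residue) / 10**scale_exp), and
    ``modulus`` the n it was encoded under.  Scale is metadata carried
    alongside ciphertexts, never baked into them: the product of two
    scale-4 encodings is a scale-8 integer, and the sign of a dot product
    is invariant to that positive factor.
    """

    residue: int
    scale_exp: int
    modulus: int

    def decode(self) -> float:
        return decode(self.residue, self.scale_exp, self.modulus)


def encode(x: float, scale_exp: int = DEFAULT_SCALE_EXP, *, n: int) -> EncodedScalar:
    """Map a real x to round(x * 10^scale_exp) mod n, sign via n - |.|."""
    scaled = round(abs(x) * 10**scale_exp)
    if 2 * scaled >= n:
        raise FixedPointOverflow(
            f"|{x}| * 10^{scale_exp} = {scaled} is not below n/2; use a larger key"
        )
    residue = scaled if x >= 0 else (n - scaled) % n
    return EncodedScalar(residue=residue, scale_exp=scale_exp, modulus=n)


def signed_value(m: int, n: int) -> int:
    """Interpret a residue in [0, n) as a signed integer in (-n/2, n/2]."""
    if not 0 <= m < n:
        raise ValueError("residue outside [0, n)")
    return m if 2 * m <= n else m - n


def decode(m: int, scale_exp: int = DEFAULT_SCALE_EXP, n: int | None = None) -> float:
    """Inverse of :func:`encode`: signed residue divided by the scale."""
    if n is None:
        raise ValueError("modulus n is required")
    return signed_value(m, n) / 10**scale_exp
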