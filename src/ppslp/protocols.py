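"""Secure multiplication (SM) and lightweight secure multiplication (LSM).

Both protocols let a party C1, holding only ciphertexts under C2's public
key, obtain a ciphertext of a product without learning the operands and
without revealing them to the key holder C2.  The trick is additive
blinding: C1 adds secret random residues homomorphically before handing
ciphertexts to C2, so everything C2 decrypts is masked; C1 then cancels
the cross terms with homomorphic correction factors.

SM multiplies one encrypted pair per round-trip.  LSM computes an entire
encrypted inner product Σ x_j·w_j in a single round: C1 blinds all 2d
values and sends them together; C2 decrypts, sums the blinded products
into one scalar h, and returns a single ciphertext H = E(h); C1 strips
the blinding with three aggregated correction terms

    T1 = Π_j E(r_xj · r_wj)^(n-1)     (cancels Σ r_x r_w)
    T2 = Π_j E(x_j)^(n - r_wj)        (cancels Σ x r_w)
    T3 = Π_j E(w_j)^(n - r_xj)        (cancels Σ r_x w)

so that R = H · T1 · T2 · T3 decrypts to Σ x_j·w_j mod n.  All values are
residues mod n; signed semantics come from the fixed-point convention in
:mod:`ppslp.fixedpoint`.

Blinding residues are drawn fresh from [1, n-1] on every invocation and
never leave C1 in plaintext.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mpc import Party, Transcript
from .paillier import Ciphertext, decrypt, encrypt, hom_add, hom_scalar

__all__ = ["BlindingPair", "sm", "lsm", "sm_inner_product"]


@dataclass(frozen=True)
class BlindingPair:
    """The two secret masks C1 uses for one (data, weight) element."""

    r_x: int
    r_w: int


def _fresh_blinding(n: int, rng) -> int:
    # 0 is excluded: a zero mask would hand C2 the true value
    return rng.randrange(1, n)


def sm(
    parties: dict[str, Party],
    transcript: Transcript,
    cx: Ciphertext,
    cy: Ciphertext,
    record_blindings: list[BlindingPair] | None = None,
) -> Ciphertext:
    """One secure multiplication: E(x), E(y) held by C1 -> E(x*y).

    C2's view is limited to (x + r_x) mod n and (y + r_y) mod n.
    """
    c1, c2 = parties["C1"], parties["C2"]
    pk = c1.require_pk()
    sk = c2.require_sk()
    led1, led2 = transcript.ledger(c1.name), transcript.ledger(c2.name)
    n = pk.n

    # C1: blind both operands and send
    r_x = _fresh_blinding(n, c1.rng)
    r_y = _fresh_blinding(n, c1.rng)
    if record_blindings is not None:
        record_blindings.append(BlindingPair(r_x=r_x, r_w=r_y))
    x1 = hom_add(pk, cx, encrypt(pk, r_x, rng=c1.rng, ledger=led1), ledger=led1)
    y1 = hom_add(pk, cy, encrypt(pk, r_y, rng=c1.rng, ledger=led1), ledger=led1)
    transcript.send(c1.name, c2.name, [x1, y1], tag="SM.blinded_operands")

    # C2: decrypt the masked operands, multiply, re-encrypt
    h_x = decrypt(sk, pk, x1, ledger=led2)
    h_y = decrypt(sk, pk, y1, ledger=led2)
    h1 = (h_x * h_y) % n
    led2.tick("MUL")  # the masked-product multiplication mod n
    H = encrypt(pk, h1, rng=c2.rng, ledger=led2)
    transcript.send(c2.name, c1.name, [H], tag="SM.masked_product")

    # C1: strip the cross terms
    s1 = hom_scalar(pk, cx, n - r_y, ledger=led1)
    s2 = hom_scalar(pk, cy, n - r_x, ledger=led1)
    s3 = hom_scalar(
        pk, encrypt(pk, (r_x * r_y) % n, rng=c1.rng, ledger=led1), n - 1, ledger=led1
    )
    out = hom_add(pk, hom_add(pk, hom_add(pk, H, s1, ledger=led1), s2, ledger=led1), s3, ledger=led1)
    return out


def lsm(
    parties: dict[str, Party],
    transcript: Transcript,
    cx: list[Ciphertext],
    cw: list[Ciphertext],
    record_blindings: list[BlindingPair] | None = None,
) -> Ciphertext:
    """Encrypted inner product of two ciphertext vectors in one round."""
    if len(cx) != len(cw):
        raise ValueError(f"dimension mismatch: {len(cx)} vs {len(cw)}")
    if not cx:
        raise ValueError("empty input vectors")
    c1, c2 = parties["C1"], parties["C2"]
    pk = c1.require_pk()
    sk = c2.require_sk()
    led1, led2 = transcript.ledger(c1.name), transcript.ledger(c2.name)
    n = pk.n
    d = len(cx)

    # C1 step 1: blind every element of both vectors, one message for all
    blindings = [
        BlindingPair(r_x=_fresh_blinding(n, c1.rng), r_w=_fresh_blinding(n, c1.rng))
        for _ in range(d)
    ]
    if record_blindings is not None:
        record_blindings.extend(blindings)
    X = [
        hom_add(pk, cx[j], encrypt(pk, blindings[j].r_x, rng=c1.rng, ledger=led1), ledger=led1)
        for j in range(d)
    ]
    W = [
        hom_add(pk, cw[j], encrypt(pk, blindings[j].r_w, rng=c1.rng, ledger=led1), ledger=led1)
        for j in range(d)
    ]
    transcript.send(c1.name, c2.name, X + W, tag="LSM.step1")

    # C2 step 2: decrypt all masked values, sum the products, return one H
    x_masked = [decrypt(sk, pk, Xj, ledger=led2) for Xj in X]
    w_masked = [decrypt(sk, pk, Wj, ledger=led2) for Wj in W]
    h = sum(xm * wm for xm, wm in zip(x_masked, w_masked)) % n
    led2.tick("MUL", d)  # the d masked-product multiplications mod n
    H = encrypt(pk, h, rng=c2.rng, ledger=led2)
    transcript.send(c2.name, c1.name, [H], tag="LSM.step2")

    # C1 step 3: aggregated correction terms
    T1 = T2 = T3 = None
    for j, b in enumerate(blindings):
        t1 = hom_scalar(
            pk,
            encrypt(pk, (b.r_x * b.r_w) % n, rng=c1.rng, ledger=led1),
            n - 1,
            ledger=led1,
        )
        t2 = hom_scalar(pk, cx[j], n - b.r_w, ledger=led1)
        t3 = hom_scalar(pk, cw[j], n - b.r_x, ledger=led1)
        T1 = t1 if T1 is None else hom_add(pk, T1, t1, ledger=led1)
        T2 = t2 if T2 is None else hom_add(pk, T2, t2, ledger=led1)
        T3 = t3 if T3 is None else hom_add(pk, T3, t3, ledger=led1)
    R = hom_add(pk, hom_add(pk, hom_add(pk, H, T1, ledger=led1), T2, ledger=led1), T3, ledger=led1)
    return R


def sm_inner_product(
    parties: dict[str, Party],
    transcript: Transcript,
    cx: list[Ciphertext],
    cw: list[Ciphertext],
) -> Ciphertext:
    """Inner product by composing d SM calls; the d-round baseline LSM beats."""
    if len(cx) != len(cw):
        raise ValueError(f"dimension mismatch: {len(cx)} vs {len(cw)}")
    if not cx:
        raise ValueError("empty input vectors")
    pk = parties["C1"].require_pk()
    led1 = transcript.ledger(parties["C1"].name)
    acc = None
    for cxj, cwj in zip(cx, cw):
        prod = sm(parties, transcript, cxj, cwj)
        acc = prod if acc is None else hom_add(pk, acc, prod, ledger=led1)
    return acc
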