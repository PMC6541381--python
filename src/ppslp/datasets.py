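"""Synthetic clinical datasets, CSV round-tripping, and dataset encryption.

The generator emulates the structure of small clinical benchmark tables
(hundreds of rows, 6-13 small-integer attributes, two classes): it plants
a random integer separating hyperplane, samples attribute vectors
uniformly from an integer range, rejects samples inside the margin, and
labels the rest by the side they fall on.  With zero label noise the
result is linearly separable by construction, so the perceptron
convergence theorem applies and training accuracy of a converged model
is exactly 100% — a crisp property two Gaussian blobs would not give.

Datasets travel as plain CSV (header row, x1..xd columns plus label and
disease_index) or, encrypted, as JSON lines with a header record carrying
the public key and the fixed-point scale.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass

import pandas as pd

from .fixedpoint import encode, signed_value
from .paillier import Ciphertext, PrivateKey, PublicKey, decrypt, encrypt
from .training import EncryptedSample, LabeledSample, sign_fn

__all__ = [
    "SynthSpec",
    "generate",
    "read_csv",
    "write_csv",
    "encrypt_samples",
    "write_encrypted_jsonl",
    "read_encrypted_jsonl",
    "decrypt_samples",
]

_REJECTION_BUDGET_PER_SAMPLE = 1000


@dataclass(frozen=True)
class SynthSpec:
    """Shape and difficulty of a synthetic clinical table.

    Defaults mirror a typical small tumour-cytology table: 9 attributes
    on an integer 1-10 scale, two classes, 7:3 train/test split.
    `margin` is the geometric half-width of the empty band around the
    planted hyperplane, in units of distance from the plane (the quantity
    the perceptron mistake bound is stated in); any margin > 0 with zero
    noise guarantees separability, and the default of 3 reflects the
    strong class separation typical of curated diagnostic tables.
    `label_noise` flips each label independently with that probability.
    """

    n_samples: int = 100
    d: int = 9
    attr_range: tuple[int, int] = (1, 10)
    margin: float = 3.0
    label_noise: float = 0.0
    seed: int | None = None
    split_ratio: tuple[int, int] = (7, 3)


def _planted_separator(d: int, rng: random.Random) -> list[int]:
    # small nonzero integer weights: realistic attribute effects, exact arithmetic
    return [rng.choice([-3, -2, -1, 1, 2, 3]) for _ in range(d)]


def generate(
    spec: SynthSpec,
) -> tuple[list[LabeledSample], list[LabeledSample], list[int]]:
    """Draw a labelled table; returns (train, test, planted_w).

    Labels are sign(planted_w·x - θ) with θ at the hyperplane's expected
    value over the attribute box, so both classes are populated.
    """
    if spec.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if spec.d < 1:
        raise ValueError("d must be >= 1")
    rng = random.Random(spec.seed)
    lo, hi = spec.attr_range
    w = _planted_separator(spec.d, rng)
    theta = round(sum(w) * (lo + hi) / 2)
    # geometric margin: the empty band scales with ||w||, so `margin` is
    # the plane-to-sample distance the convergence bound is stated in
    band = spec.margin * math.sqrt(sum(wj * wj for wj in w))

    samples: list[LabeledSample] = []
    budget = _REJECTION_BUDGET_PER_SAMPLE * spec.n_samples
    while len(samples) < spec.n_samples:
        if budget <= 0:
            raise RuntimeError(
                "rejection budget exhausted; the margin is infeasible for this "
                "attribute range — try a smaller margin"
            )
        budget -= 1
        x = tuple(rng.randint(lo, hi) for _ in range(spec.d))
        z = sum(wj * xj for wj, xj in zip(w, x)) - theta
        if abs(z) < band:
            continue
        label = sign_fn(z)
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = -label
        samples.append(LabeledSample(x=x, label=label))

    if len({s.label for s in samples}) < 2:
        raise RuntimeError(
            "generated table is single-class; re-seed or widen the attribute range"
        )

    rng.shuffle(samples)
    a, b = spec.split_ratio
    n_train = round(spec.n_samples * a / (a + b))
    return samples[:n_train], samples[n_train:], w


# ---------------------------------------------------------------------------
# CSV


def write_csv(samples: list[LabeledSample], path: str) -> None:
    d = len(samples[0].x) if samples else 0
    df = pd.DataFrame(
        [list(s.x) + [s.label, s.disease_index] for s in samples],
        columns=[f"x{j + 1}" for j in range(d)] + ["label", "disease_index"],
    )
    df.to_csv(path, index=False)


def read_csv(
    path: str,
    label_column: str = "label",
    label_map: dict[int, int] | None = None,
) -> list[LabeledSample]:
    """Load a labelled table; labels must be in {-1, +1} after `label_map`.

    `label_map` accommodates 0/1-coded files ({0: -1, 1: 1}).
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"missing label column {label_column!r}")
    feat_cols = [c for c in df.columns if c not in (label_column, "disease_index")]
    samples = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            x = tuple(int(rec[c]) for c in feat_cols)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric attribute at row {row_num}") from exc
        label = int(rec[label_column])
        if label_map is not None:
            label = label_map.get(label, label)
        if label not in (-1, 1):
            raise ValueError(f"invalid label {label} at row {row_num}")
        samples.append(
            LabeledSample(x=x, label=label, disease_index=int(rec.get("disease_index", 0)))
        )
    return samples


# ---------------------------------------------------------------------------
# encryption


def encrypt_samples(
    samples: list[LabeledSample],
    pk: PublicKey,
    scale_exp: int = 0,
    rng: random.Random | None = None,
) -> list[EncryptedSample]:
    """Encrypt every attribute under pk; labels stay plaintext."""
    out = []
    for s in samples:
        cx = tuple(
            encrypt(pk, encode(v, scale_exp, n=pk.n).residue, rng=rng) for v in s.x
        )
        out.append(EncryptedSample(cx=cx, label=s.label, disease_index=s.disease_index))
    return out


def decrypt_samples(
    enc: list[EncryptedSample], sk: PrivateKey, pk: PublicKey, scale_exp: int = 0
) -> list[LabeledSample]:
    scale = 10**scale_exp
    out = []
    for s in enc:
        x = tuple(signed_value(decrypt(sk, pk, c), pk.n) // scale for c in s.cx)
        out.append(LabeledSample(x=x, label=s.label, disease_index=s.disease_index))
    return out


def write_encrypted_jsonl(
    enc: list[EncryptedSample], pk: PublicKey, scale_exp: int, path: str
) -> None:
    """Header record {n, g, scale_exp, d}, then one record per sample."""
    d = len(enc[0].cx) if enc else 0
    with open(path, "w") as f:
        f.write(json.dumps({"n": hex(pk.n), "g": hex(pk.g), "scale_exp": scale_exp, "d": d}) + "\n")
        for s in enc:
            f.write(
                json.dumps(
                    {
                        "disease_index": s.disease_index,
                        "label": s.label,
                        "ciphertexts": [hex(c.value) for c in s.cx],
                    }
                )
                + "\n"
            )


def read_encrypted_jsonl(path: str) -> tuple[list[EncryptedSample], PublicKey, int]:
    with open(path) as f:
        header = json.loads(f.readline())
        pk = PublicKey(n=int(header["n"], 16), g=int(header["g"], 16))
        enc = []
        for line in f:
            rec = json.loads(line)
            cx = tuple(Ciphertext(value=int(h, 16), key_id=pk.key_id) for h in rec["ciphertexts"])
            enc.append(
                EncryptedSample(cx=cx, label=rec["label"], disease_index=rec["disease_index"])
            )
    return enc, pk, header["scale_exp"]
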