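"""Single-layer perceptron training, in the plain and in the encrypted domain.

The plaintext trainer is the classical mistake-driven perceptron over
integer features: predict sign(w·x), and on a mistake update
w <- w + η·O·x with label O in {-1, +1}.  It doubles as the exact oracle
for the encrypted trainer.

The encrypted trainer splits the same loop between two parties.  The
Cloud holds the encrypted samples Cx and the encrypted weights Cw, all
under the Hospital's public key; the Hospital holds the private key.  Per
sample, the Cloud obtains R = E(w·x) via the one-round LSM protocol and
sends it to the Hospital, which decrypts, applies sign, and returns the
single bit S.  On a mismatch the Cloud updates every weight ciphertext
homomorphically:

    exp = η        if O = +1
    exp = n - η    if O = -1          (additive inverse of η mod n)
    Cw_j <- Cw_j · Cx_j^exp           i.e.  w_j <- w_j + η·O·x_j

so the decrypted weights track the plaintext perceptron exactly, epoch by
epoch — not merely approximately.  The Hospital never sees features,
weights, or labels during training; its entire view is the blinded LSM
traffic plus the sign bits it computes itself.

η must be a positive integer (default 1): ciphertext exponents are
integers, and perceptron decisions are invariant under positive rescaling
of η and w together, so integer η loses no generality.  Labels are held
by the Cloud in plaintext — an accepted leakage of the scheme, since the
label alone identifies no patient.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field, replace

from .fixedpoint import signed_value
from .mpc import Party, Transcript
from .paillier import Ciphertext, PrivateKey, PublicKey, decrypt, encrypt, hom_add, hom_scalar
from .protocols import lsm

__all__ = [
    "LabeledSample",
    "EncryptedSample",
    "Model",
    "TrainConfig",
    "sign_fn",
    "initial_weights",
    "train_plain",
    "train_encrypted",
    "train_all_diseases",
    "decrypt_model",
    "RangeGuardError",
]


class RangeGuardError(OverflowError):
    """Working values could wrap around n/2; a larger key is required."""


@dataclass(frozen=True)
class LabeledSample:
    """Integer-encoded feature vector with a {-1, +1} label."""

    x: tuple[int, ...]
    label: int
    disease_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"label must be -1 or +1, got {self.label}")
        object.__setattr__(self, "x", tuple(int(v) for v in self.x))


@dataclass(frozen=True)
class EncryptedSample:
    """Ciphertexts of one sample's features; label stays in plaintext."""

    cx: tuple[Ciphertext, ...]
    label: int
    disease_index: int = 0


@dataclass
class Model:
    """A per-disease weight vector, plaintext integers or ciphertexts."""

    w: list
    disease_index: int = 0
    scale_exp: int = 0
    trained_epochs: int = 0
    converged: bool = False
    weight_history: list[list[int]] | None = None

    @property
    def encrypted(self) -> bool:
        return bool(self.w) and isinstance(self.w[0], Ciphertext)


@dataclass(frozen=True)
class TrainConfig:
    """Knobs shared by both trainers.

    eta: positive integer learning rate.  iteration_max: epoch cap
    (training also stops at the first update-free epoch).  order:
    "sequential" or "shuffle" (re-shuffled each epoch from `seed`).
    bias: prepend a constant feature x0 = 10**scale_exp, realizing a
    trainable threshold w0 = -θ.  x_bound: declared bound on |x_j|, used
    by the overflow guard.  record_history: snapshot (decrypted) weights
    after every epoch.
    """

    eta: int = 1
    iteration_max: int = 100
    order: str = "sequential"
    bias: bool = False
    seed: int | None = None
    scale_exp: int = 0
    x_bound: int = 10
    record_history: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.eta, int) and self.eta >= 1):
            raise ValueError("eta must be a positive integer")
        if self.iteration_max < 1:
            raise ValueError("iteration_max must be >= 1")
        if self.order not in ("sequential", "shuffle"):
            raise ValueError("order must be 'sequential' or 'shuffle'")


def sign_fn(z: int) -> int:
    """Activation: +1 for z >= 0, else -1 (a zero score predicts disease)."""
    return 1 if z >= 0 else -1


def initial_weights(d: int, rng: random.Random, bound: int = 5) -> list[int]:
    """Random integer weights in [-bound, bound], not all zero."""
    while True:
        w = [rng.randint(-bound, bound) for _ in range(d)]
        if any(w):
            return w


def _bias_value(cfg: TrainConfig) -> int:
    return 10**cfg.scale_exp


def _visit_order(n: int, epoch_rng: random.Random | None) -> list[int]:
    order = list(range(n))
    if epoch_rng is not None:
        epoch_rng.shuffle(order)
    return order


def _check_range(d: int, w_bound: int, cfg: TrainConfig, n: int | None) -> None:
    if n is not None and 2 * d * w_bound * cfg.x_bound >= n:
        raise RangeGuardError(
            "inner product could exceed n/2 and wrap; use a larger key "
            f"(d={d}, |w|<={w_bound}, |x|<={cfg.x_bound})"
        )


def train_plain(
    samples: list[LabeledSample],
    cfg: TrainConfig,
    initial_w: list[int] | None = None,
    modulus: int | None = None,
) -> Model:
    """Train a perceptron in the clear; exact integer arithmetic throughout.

    When `modulus` is given the same overflow guard as the encrypted
    trainer is applied, so the two paths fail identically as well as
    succeed identically.
    """
    if not samples:
        raise ValueError("no training samples")
    d0 = len(samples[0].x)
    if any(len(s.x) != d0 for s in samples):
        raise ValueError("inconsistent feature dimensions")
    xs = [((_bias_value(cfg),) + s.x if cfg.bias else s.x) for s in samples]
    d = len(xs[0])

    init_rng = random.Random(cfg.seed)
    w = list(initial_w) if initial_w is not None else initial_weights(d, init_rng)
    if len(w) != d:
        raise ValueError("initial weight dimension mismatch")
    order_rng = random.Random(cfg.seed) if cfg.order == "shuffle" else None

    w_bound = max(abs(v) for v in w)
    history: list[list[int]] = []
    epochs = 0
    converged = False
    for _ in range(cfg.iteration_max):
        _check_range(d, w_bound, cfg, modulus)
        epochs += 1
        updates = 0
        for i in _visit_order(len(xs), order_rng):
            x, o = xs[i], samples[i].label
            if sign_fn(sum(wj * xj for wj, xj in zip(w, x))) != o:
                w = [wj + cfg.eta * o * xj for wj, xj in zip(w, x)]
                updates += 1
        w_bound = max(abs(v) for v in w)
        if cfg.record_history:
            history.append(list(w))
        if updates == 0:
            converged = True
            break
    return Model(
        w=w,
        disease_index=samples[0].disease_index,
        scale_exp=cfg.scale_exp,
        trained_epochs=epochs,
        converged=converged,
        weight_history=history if cfg.record_history else None,
    )


def train_encrypted(
    cloud: Party,
    hospital: Party,
    enc_samples: list[EncryptedSample],
    cfg: TrainConfig,
    initial_w: list[int] | None = None,
    transcript: Transcript | None = None,
) -> tuple[Model, Transcript]:
    """Train over ciphertexts; decrypted weights equal `train_plain`'s.

    The Hospital encrypts the initial weights once; thereafter the Cloud
    holds the authoritative Cw and updates it homomorphically, so updates
    accumulate across epochs.  The initial weights default to the same
    seeded draw `train_plain` uses, keeping the two trainers in lockstep
    under a shared config.
    """
    if not enc_samples:
        raise ValueError("no training samples")
    pk = hospital.require_pk()
    sk = hospital.require_sk()
    n = pk.n
    if transcript is None:
        transcript = Transcript()
    led_c, led_h = transcript.ledger(cloud.name), transcript.ledger(hospital.name)

    cxs: list[tuple[Ciphertext, ...]] = []
    for s in enc_samples:
        cx = s.cx
        if cfg.bias:
            # the constant feature is public, so the Cloud may encrypt it itself
            cx = (encrypt(pk, _bias_value(cfg) % n, rng=cloud.rng, ledger=led_c),) + cx
        cxs.append(cx)
    d = len(cxs[0])
    if any(len(cx) != d for cx in cxs):
        raise ValueError("inconsistent feature dimensions")

    init_rng = random.Random(cfg.seed)
    w0 = list(initial_w) if initial_w is not None else initial_weights(d, init_rng)
    if len(w0) != d:
        raise ValueError("initial weight dimension mismatch")
    # Hospital encrypts the initial model and hands it to the Cloud
    cw = [encrypt(pk, v % n, rng=hospital.rng, ledger=led_h) for v in w0]
    transcript.send(hospital.name, cloud.name, list(cw), tag="train.initial_weights")

    order_rng = random.Random(cfg.seed) if cfg.order == "shuffle" else None
    w_bound = max(abs(v) for v in w0)
    history: list[list[int]] = []
    epochs = 0
    converged = False
    for _ in range(cfg.iteration_max):
        _check_range(d, w_bound, cfg, n)
        epochs += 1
        updates = 0
        for i in _visit_order(len(cxs), order_rng):
            cx, o = cxs[i], enc_samples[i].label
            # Cloud computes E(w·x) in one round and forwards it
            R = lsm({"C1": cloud, "C2": hospital}, transcript, list(cx), cw)
            transcript.send(cloud.name, hospital.name, [R], tag="train.score")
            # Hospital: decrypt, sign, return the single bit S
            S = sign_fn(signed_value(decrypt(sk, pk, R, ledger=led_h), n))
            transcript.send(hospital.name, cloud.name, [S], tag="train.sign")
            if S != o:
                exp = cfg.eta if o == 1 else n - cfg.eta
                cw = [
                    hom_add(pk, cwj, hom_scalar(pk, cxj, exp, ledger=led_c), ledger=led_c)
                    for cwj, cxj in zip(cw, cx)
                ]
                updates += 1
        w_bound += updates * cfg.eta * cfg.x_bound
        if cfg.record_history:
            history.append([signed_value(decrypt(sk, pk, c), n) for c in cw])
        if updates == 0:
            converged = True
            break
    model = Model(
        w=cw,
        disease_index=enc_samples[0].disease_index,
        scale_exp=cfg.scale_exp,
        trained_epochs=epochs,
        converged=converged,
        weight_history=history if cfg.record_history else None,
    )
    return model, transcript


def decrypt_model(model: Model, sk: PrivateKey, pk: PublicKey) -> Model:
    """Signed plaintext view of an encrypted model (Hospital-side)."""
    if not model.encrypted:
        return model
    w = [signed_value(decrypt(sk, pk, c), pk.n) for c in model.w]
    return replace(model, w=w)


def train_all_diseases(
    cloud: Party,
    hospital: Party,
    enc_samples: list[EncryptedSample],
    disease_indices: list[int],
    cfg: TrainConfig,
) -> list[Model]:
    """One independent encrypted model per disease index."""
    models = []
    for k in disease_indices:
        subset = [s for s in enc_samples if s.disease_index == k]
        if not subset:
            warnings.warn(f"disease index {k} has no samples; skipped", stacklevel=2)
            continue
        model, _ = train_encrypted(cloud, hospital, subset, cfg)
        models.append(model)
    return models
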