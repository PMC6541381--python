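"""Disease prediction for an undiagnosed patient.

The patient encrypts symptom values under the Hospital's public key and
submits them.  Prediction is deliberately plaintext-side at the Hospital:
it decrypts the symptoms, scores them against its plaintext model
(s = Σ x_j·w_j, label = sign(s), with s = 0 predicting disease), and
returns the verdict encrypted under the *patient's* public key, so only
the patient can read it.  Inside the returned ciphertext the label is
encoded 1 for "suffers from the disease" and 0 for "does not".
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .fixedpoint import signed_value
from .mpc import Party
from .paillier import Ciphertext, PublicKey, decrypt, encrypt
from .training import Model, sign_fn

__all__ = ["PredictionResult", "predict", "encrypt_symptoms"]

RESULT_ENCODING = {1: 1, -1: 0}  # label -> Paillier plaintext


@dataclass(frozen=True)
class PredictionResult:
    label: int  # -1 or +1
    ciphertext_for_patient: Ciphertext
    disease_index: int


def encrypt_symptoms(
    x: list[int], hospital_pk: PublicKey, rng: random.Random | None = None
) -> list[Ciphertext]:
    """Patient-side: encrypt integer-encoded symptoms under PK_h."""
    n = hospital_pk.n
    return [encrypt(hospital_pk, v % n, rng=rng) for v in x]


def predict(
    hospital: Party,
    model: Model,
    c_symptoms: list[Ciphertext],
    patient_pk: PublicKey,
) -> PredictionResult:
    """Score encrypted symptoms with a plaintext model; answer under PK_up."""
    if model.encrypted:
        raise ValueError("prediction requires a plaintext (decrypted) model")
    if len(c_symptoms) != len(model.w):
        raise ValueError(
            f"dimension mismatch: {len(c_symptoms)} symptoms vs {len(model.w)} weights"
        )
    pk = hospital.require_pk()
    sk = hospital.require_sk()
    x = [signed_value(decrypt(sk, pk, c), pk.n) for c in c_symptoms]
    s = sum(xj * wj for xj, wj in zip(x, model.w))
    label = sign_fn(s)
    c_result = encrypt(
        patient_pk, RESULT_ENCODING[label], rng=hospital.rng
    )
    return PredictionResult(
        label=label, ciphertext_for_patient=c_result, disease_index=model.disease_index
    )
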