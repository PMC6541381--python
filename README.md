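# ppslp — privacy-preserving perceptron training over Paillier ciphertexts

`ppslp` implements a two-party scheme for training a clinical risk
classifier on encrypted patient data.  A **cloud server** stores
Paillier ciphertexts of patient feature vectors and trains a
single-layer perceptron on them; the **hospital**, which holds the
private key, assists only by decrypting blinded intermediate values and
returning sign bits.  Neither raw features nor model weights ever
appear in the clear at the cloud, and a querying patient receives their
diagnosis encrypted under their own key.

It is aimed at people studying or teaching secure computation for
clinical decision support: everything runs in-process with full
transcripts, seeded randomness, and exact plaintext oracles, so every
protocol step can be inspected and verified.

## The scheme in brief

Paillier encryption is additively homomorphic: with plaintexts in Z_n,

    D(E(a) · E(b) mod n²) = a + b mod n,     D(E(a)^k mod n²) = k·a mod n.

Signed values use the fixed-point convention x ↦ round(x·10^s), with
negatives as n − |·| and the midpoint n/2 as the sign boundary.

The classifier is sign(w·x) with the mistake-driven update
w ← w + η·O·x for labels O ∈ {−1, +1}.  Two building blocks make this
trainable over ciphertexts:

- **LSM (lightweight secure multiplication)** — computes E(Σ x_j·w_j)
  from E(x_j), E(w_j) in a *single* message exchange: the cloud masks
  all 2d values additively, the hospital decrypts and returns the one
  masked sum E(h), and the cloud strips the masks with three aggregated
  homomorphic corrections T1·T2·T3.  The element-wise SM baseline needs
  d exchanges for the same result.
- **Homomorphic update** — on a mismatch (hospital's sign bit S ≠ O)
  the cloud sets Cw_j ← Cw_j · Cx_j^exp with exp = η (O = +1) or
  exp = n − η (O = −1), which is exactly w_j ← w_j + η·O·x_j under
  encryption.

Because every step is exact ring arithmetic, the decrypted
encrypted-domain weights equal the plaintext perceptron's weights
element-wise after every epoch — the test suite asserts equality, not
approximation.

## Worked example

```python
import random
from ppslp import (keygen, SynthSpec, generate, encrypt_samples, TrainConfig,
                   train_encrypted, train_plain, decrypt_model, sign_fn)
from ppslp.mpc import Party

pk, sk = keygen(256, seed=1)                      # 256-bit primes
train, test, planted = generate(SynthSpec(n_samples=100, d=9, seed=42))

cfg = TrainConfig(eta=1, iteration_max=100, seed=42)
enc = encrypt_samples(train, pk, rng=random.Random(0))
cloud    = Party("Cloud", pk=pk, seed=1)          # never sees plaintext
hospital = Party("Hospital", pk=pk, sk=sk, seed=2)

model, transcript = train_encrypted(cloud, hospital, enc, cfg)
dec = decrypt_model(model, sk, pk)
print(dec.w, dec.trained_epochs, dec.converged)
print(train_plain(train, cfg).w)                  # the plaintext oracle
```

prints

```
[19, -14, -16, 22, -5, -13, -1, 0, 10] 2 True
[19, -14, -16, 22, -5, -13, -1, 0, 10]
```

— the encrypted-domain and plaintext weight vectors are identical, here
after 2 epochs of training 70 samples against the planted separator
`[3, -3, -3, 3, -1, -2, -2, -2, 3]`.  The transcript records 280
message rounds (one LSM round per sample visit plus the sign exchange)
and per-party EXP/MUL/DIV tallies.  The resulting classifier labels all
30 held-out samples correctly, and a patient query comes back as a
ciphertext only the patient can open (1 = disease, 0 = not).

The same pipeline is scriptable from the shell:

```bash
ppslp keygen --bits 256 --seed 1 --pub pk.json --priv sk.json
ppslp simulate-data --n 100 --d 9 --seed 42 --train-out train.csv --test-out test.csv
ppslp encrypt --pub pk.json --in train.csv --out enc.jsonl --seed 0
ppslp train --in enc.jsonl --pub pk.json --priv sk.json --seed 42 --out model.json
ppslp predict --model model.json --pub pk.json --priv sk.json --in test.csv
ppslp benchmark --dims 2,4,8,16
```

## Layout

| module | contents |
|---|---|
| `ppslp.paillier` | keygen / encrypt / decrypt, homomorphic operators, key files |
| `ppslp.fixedpoint` | signed fixed-point encode / decode / signed_value |
| `ppslp.mpc` | Party, Message, Transcript, round counting, op ledgers |
| `ppslp.protocols` | SM and one-round LSM secure inner product |
| `ppslp.training` | plaintext perceptron oracle + two-party encrypted training |
| `ppslp.prediction` | hospital-side scoring, verdict under the patient's key |
| `ppslp.datasets` | synthetic clinical tables, CSV and encrypted-JSONL I/O |
| `ppslp.cli` | `ppslp` console script |

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and known limitations (semi-honest adversaries only; labels
and per-sample sign bits are accepted leakage of the scheme).
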