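# Methods

## The problem

A hospital wants a linear disease classifier trained on patient records it
must not see in the clear, using storage and compute it does not own.  The
scheme splits the work between two semi-honest parties: a **Cloud** that
stores only ciphertexts of patient features, and the **Hospital** that
holds the Paillier private key but never receives raw training data.
Diagnosed patients encrypt their feature vectors under the hospital's
public key and deposit them, with a plaintext ±1 diagnosis label, at the
cloud.  Undiagnosed patients later query the trained model; the verdict
returns encrypted under the *patient's* key, so not even an eavesdropper
on the reply learns it.

## Cryptographic substrate

Standard Paillier over n = pq: E(m) = g^m · r^n mod n², D(c) =
L(c^λ mod n²)·μ mod n, with the additive identities D(E(a)·E(b)) = a+b
and D(E(a)^k) = k·a (all mod n).  Defaults: g = n+1 (always a valid
generator, and makes g^m a single multiplication), blinding r uniform on
[1, n−1] excluding residues sharing a factor with n, primality by
`sympy.isprime` on candidates from a seeded RNG so key generation is
reproducible.  Decryption uses the mathematically equivalent prime-wise
CRT evaluation when the private key carries p and q; the textbook formula
remains as the fallback and the two are tested for agreement.

Signed values use the symmetric fixed-point convention: x ↦
round(x·10^s) for x ≥ 0 and n − round(|x|·10^s) otherwise, decoded with
the midpoint rule (residues strictly above n/2 are negative).  Scale s is
metadata, never baked into ciphertexts; the product of two scale-s
encodings is a scale-2s integer, and a sign test is invariant to that
positive factor.  Encoding requires |x|·10^s < n/2, enforced by an
explicit guard — with 256-bit primes the headroom is astronomically
large for clinical-scale integers.

## One-round secure inner product (LSM)

To score one sample the cloud needs E(Σ x_j w_j) from E(x_j) and E(w_j).
Element-wise secure multiplication (SM) costs one message exchange per
coordinate.  The LSM protocol does the whole vector in one exchange:

1. C1 (cloud) adds fresh uniform masks homomorphically — X_j =
   E(x_j + r_xj), W_j = E(w_j + r_wj) — and sends all 2d ciphertexts at
   once.
2. C2 (hospital) decrypts, computes the single scalar
   h = Σ (x_j + r_xj)(w_j + r_wj) mod n, and returns H = E(h).
3. C1 cancels every cross term with three aggregated corrections
   T1 = Π E(r_xj·r_wj)^(n−1), T2 = Π E(x_j)^(n−r_wj),
   T3 = Π E(w_j)^(n−r_xj); then R = H·T1·T2·T3 = E(Σ x_j w_j).

Correctness is exact modular arithmetic, no approximation.  C2's entire
view is uniformly masked values; tests assert that everything C2
decrypts differs from the truth by exactly its secret mask and that
distinct blinding seeds give disjoint views with identical outputs.
Masks are drawn fresh per invocation; reuse is forbidden by contract.

Cost accounting: ledgers tick one EXP per ciphertext exponentiation
(two per encryption), one MUL per multiplication mod n² (plus the
masked-product multiplications mod n at C2, which the scheme's cost
model attributes to the same ledger), one DIV per decryption.  Totals
are affine in d — measured slopes: C1 9·EXP and 8·MUL per added
dimension, C2 2·EXP, 1·MUL, 2·DIV — with exactly one round regardless
of d, versus d rounds for the SM composition.

## Encrypted perceptron training

The classifier is a single-layer perceptron, sign(w·x) with sign(0) = +1
("a zero score predicts disease").  Plaintext rule: on a mistake,
w ← w + η·O·x.  In the encrypted domain the cloud obtains R = E(w·x)
via LSM, the hospital returns the single bit S = sign(D(R)), and on
S ≠ O the cloud updates each weight ciphertext as Cw_j ← Cw_j ·
Cx_j^exp with exp = η for O = +1 and exp = n − η for O = −1 (the
additive inverse of η, realizing subtraction).  Because every step is
exact ring arithmetic, decrypted encrypted-domain weights equal the
plaintext perceptron's weights *element-wise after every epoch* — the
suite asserts equality, not closeness — and the two final classifiers
agree on every input.

Design choices:

- **η is a positive integer (default 1).**  Ciphertext exponents must be
  integers, and perceptron decisions are invariant under positive
  rescaling of η and w together, so nothing is lost.
- **Model custody.**  The hospital draws random not-all-zero initial
  weights, encrypts them once, and hands them to the cloud; the cloud
  holds the authoritative Cw and updates it across epochs.  Re-uploading
  weights each epoch would discard the cloud's homomorphic updates.
- **Stopping.**  First update-free epoch, or the epoch cap
  (`iteration_max`, default 100).
- **Visit order.**  Deterministic sequential by default; optional
  per-epoch shuffle from the configuration seed.  Both trainers consume
  identical order and initialization streams, which is what makes the
  lockstep comparison meaningful.
- **Bias.**  An optional constant feature x₀ = 10^s implements a
  trainable threshold w₀ = −θ; off by default.  The constant is public,
  so the cloud encrypts it itself.
- **Overflow guard.**  Before each epoch both trainers check
  2·d·max|w|·max|x| < n (with max|w| tracked as a worst-case bound,
  since the cloud cannot see w) and raise rather than risk silent
  wraparound.
- **Accepted leakage.**  Labels are stored in plaintext at the cloud and
  the hospital learns the per-sample sign bit during training; both are
  properties of the original scheme, documented rather than "fixed".

Prediction is deliberately plaintext-side at the hospital (it decrypts
the querying patient's symptoms, scores, and re-encrypts the verdict
under the patient's key, 1 = disease / 0 = not); no encrypted-domain
evaluation is attempted because the hospital legitimately holds both
the model and the decryption key.

## Synthetic data

Real benchmark tables of this kind (breast-cancer cytology, heart
disease, acute inflammations) are small: 120-683 rows, 6-13 integer
attributes, two classes, typically split 7:3.  The generator emulates
that shape: attributes uniform on an integer range (default 1-10, 9
dimensions, 100 samples), labels from a planted integer hyperplane with
entries in ±{1,2,3} and threshold at the hyperplane's expected value
over the attribute box, rejection of samples within a geometric margin
band, optional independent label flips, seeded shuffle then 7:3 split.

The margin parameter is the plane-to-sample distance (band half-width
divided by ‖w‖₂) — the unit the perceptron mistake bound (R/γ)² is
stated in, so separability and convergence guarantees are explicit.
The default margin of 3 reflects the strong separation typical of
curated diagnostic tables; at that setting training converges within a
handful of epochs across seeds.  What the generator does *not* emulate:
correlated attributes, class imbalance, missing values, and the
wide-range attributes some clinical tables carry (the attribute range is
configurable for that regime).  Passing tests therefore demonstrate
protocol and training correctness, not clinical accuracy on real data.

## Problem sizes and numerics

Tests run on three key sizes: a hand-checkable n = 35 toy key for
arithmetic identities, a 64-bit modulus for fast exact protocol tests,
and 256-bit primes (512-bit n) for the end-to-end properties; production
guidance is ≥ 1024-bit primes.  The heavyweight checks use 1,000 random
plaintexts for the cryptosystem identities, 500 random signed vectors
(d ≤ 32, entries up to 10⁶) for the inner-product oracle, and a
100-sample d = 9 training study — sizes chosen to exercise the full
working range while keeping pure-Python bignum arithmetic comfortable.
All correctness assertions are exact integer equality; the only
tolerance anywhere is the half-unit bound 0.5·10^−s of fixed-point
rounding.

## Known limitations

- Semi-honest model only: no protection against parties that deviate
  from the protocol, and no formal security proofs here — transcript
  sanity checks (masking, view independence) are structural tests, not
  proofs.
- No constant-time arithmetic or side-channel hardening; keys live in
  JSON files (private key written mode 0600).
- One sample per ciphertext vector; no packing, batching, or mini-batch
  training.
- The hospital's per-sample sign bit and the plaintext labels at the
  cloud are inherent leakage of the scheme, as noted above.
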