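"""Perceptron training: plaintext oracle, encrypted lockstep, update rules."""

import random

import pytest

from ppslp.datasets import SynthSpec, encrypt_samples, generate
from ppslp.fixedpoint import signed_value
from ppslp.mpc import Party
from ppslp.paillier import decrypt
from ppslp.training import (
    EncryptedSample,
    LabeledSample,
    Model,
    RangeGuardError,
    TrainConfig,
    decrypt_model,
    sign_fn,
    train_all_diseases,
    train_encrypted,
    train_plain,
)


def _parties(small_key, seed=50):
    pk, sk = small_key
    return Party("Cloud", pk=pk, seed=seed), Party("Hospital", pk=pk, sk=sk, seed=seed + 1)


def test_sign_convention():
    assert sign_fn(0) == 1  # a zero score predicts disease
    assert sign_fn(-1) == -1
    assert sign_fn(10**8) == 1


class TestPlainPerceptron:
    def test_hand_traced_single_update(self):
        """x=(1,1), O=+1, w0=(-1,-1): one update lands on w=(0,0), which
        then scores sign(0)=+1 and matches."""
        samples = [LabeledSample(x=(1, 1), label=1)]
        m = train_plain(samples, TrainConfig(eta=1), initial_w=[-1, -1])
        assert m.w == [0, 0]
        assert m.converged
        assert m.trained_epochs == 2  # update epoch + confirming clean epoch

    def test_separating_init_is_fixed_point(self):
        samples = [LabeledSample(x=(2, 1), label=1), LabeledSample(x=(-3, -1), label=-1)]
        m = train_plain(samples, TrainConfig(), initial_w=[5, 1])
        assert m.w == [5, 1]
        assert m.trained_epochs == 1
        assert m.converged

    def test_converges_on_separable_data_with_full_accuracy(self):
        train, _, _ = generate(SynthSpec(n_samples=80, d=6, seed=1))
        m = train_plain(train, TrainConfig(seed=1))
        assert m.converged
        assert all(
            sign_fn(sum(wj * xj for wj, xj in zip(m.w, s.x))) == s.label for s in train
        )

    def test_iteration_cap_flags_nonconvergence(self):
        # XOR-style labels cannot be separated linearly
        samples = [
            LabeledSample(x=(1, 1), label=-1),
            LabeledSample(x=(-1, -1), label=-1),
            LabeledSample(x=(1, -1), label=1),
            LabeledSample(x=(-1, 1), label=1),
        ]
        m = train_plain(samples, TrainConfig(iteration_max=5), initial_w=[1, 1])
        assert not m.converged
        assert m.trained_epochs == 5

    def test_validation(self):
        with pytest.raises(ValueError):
            train_plain([], TrainConfig())
        with pytest.raises(ValueError):
            TrainConfig(eta=0)
        with pytest.raises(ValueError):
            TrainConfig(eta=0.5)
        with pytest.raises(ValueError):
            TrainConfig(order="random")
        with pytest.raises(ValueError):
            train_plain(
                [LabeledSample(x=(1,), label=1), LabeledSample(x=(1, 2), label=1)],
                TrainConfig(),
            )
        with pytest.raises(ValueError):
            LabeledSample(x=(1,), label=0)

    def test_bias_feature_learns_threshold(self):
        # one-dimensional data separable only with an offset: x >= 3 -> +1
        samples = [LabeledSample(x=(v,), label=1 if v >= 3 else -1) for v in range(1, 7)]
        plain = train_plain(samples, TrainConfig(iteration_max=200), initial_w=[0])
        biased = train_plain(
            samples, TrainConfig(iteration_max=200, bias=True), initial_w=[0, 0]
        )
        assert not plain.converged
        assert biased.converged


class TestEncryptedTraining:
    def test_single_sample_trace_matches_plaintext(self, small_key):
        pk, sk = small_key
        cloud, hospital = _parties(small_key)
        samples = [LabeledSample(x=(1, 1), label=1)]
        enc = encrypt_samples(samples, pk, rng=random.Random(1))
        model, _ = train_encrypted(cloud, hospital, enc, TrainConfig(eta=1), initial_w=[-1, -1])
        assert decrypt_model(model, sk, pk).w == [0, 0]

    def test_no_update_when_initial_weights_classify(self, small_key):
        pk, sk = small_key
        cloud, hospital = _parties(small_key)
        samples = [LabeledSample(x=(2, 1), label=1)]
        enc = encrypt_samples(samples, pk, rng=random.Random(2))
        model, _ = train_encrypted(cloud, hospital, enc, TrainConfig(), initial_w=[5, 1])
        assert decrypt_model(model, sk, pk).w == [5, 1]
        assert model.converged

    @pytest.mark.parametrize("label", [1, -1])
    def test_single_update_correctness_both_branches(self, small_key, label):
        """One mismatch update changes each decrypted weight by exactly
        eta * O * x_j — the positive branch uses exponent eta, the negative
        branch exponent n - eta."""
        pk, sk = small_key
        cloud, hospital = _parties(small_key, seed=60 + label)
        x = (3, 5, 2)
        w0 = [-label * 10, -label * 10, -label * 10]  # guarantees a mismatch
        eta = 2
        enc = encrypt_samples([LabeledSample(x=x, label=label)], pk, rng=random.Random(3))
        model, _ = train_encrypted(
            cloud, hospital, enc, TrainConfig(eta=eta, iteration_max=1), initial_w=w0
        )
        got = decrypt_model(model, sk, pk).w
        assert [g - w for g, w in zip(got, w0)] == [eta * label * xj for xj in x]

    @pytest.mark.parametrize("order", ["sequential", "shuffle"])
    def test_lockstep_with_plaintext_oracle(self, small_key, order):
        """Decrypted encrypted-domain weights equal the plaintext trainer's
        after every epoch, for sequential and shuffled visit orders."""
        pk, sk = small_key
        cloud, hospital = _parties(small_key, seed=70)
        train, _, _ = generate(SynthSpec(n_samples=40, d=5, seed=4))
        cfg = TrainConfig(seed=9, order=order, record_history=True)
        plain = train_plain(train, cfg)
        enc = encrypt_samples(train, pk, rng=random.Random(5))
        enc_model, _ = train_encrypted(cloud, hospital, enc, cfg)
        assert enc_model.weight_history == plain.weight_history
        assert decrypt_model(enc_model, sk, pk).w == plain.w
        assert enc_model.trained_epochs == plain.trained_epochs
        assert enc_model.converged == plain.converged

    def test_hospital_receives_only_ciphertexts_and_sends_signs(self, small_key):
        """The hospital's incoming payloads contain no plaintext residues;
        labels reach it only through the sign bit it computes itself."""
        pk, sk = small_key
        from ppslp.paillier import Ciphertext

        cloud, hospital = _parties(small_key, seed=80)
        train, _, _ = generate(SynthSpec(n_samples=20, d=4, seed=6))
        enc = encrypt_samples(train, pk, rng=random.Random(7))
        _, transcript = train_encrypted(cloud, hospital, enc, TrainConfig(seed=3))
        incoming = [m for m in transcript.messages if m.receiver == "Hospital"]
        assert incoming
        for m in incoming:
            assert all(isinstance(p, Ciphertext) for p in m.payload)

    def test_range_guard_fires_on_tiny_modulus(self, toy_key):
        pk, sk = toy_key
        cloud = Party("Cloud", pk=pk, seed=1)
        hospital = Party("Hospital", pk=pk, sk=sk, seed=2)
        enc = encrypt_samples(
            [LabeledSample(x=(3, 3), label=1)], pk, rng=random.Random(8)
        )
        with pytest.raises(RangeGuardError):
            train_encrypted(cloud, hospital, enc, TrainConfig(), initial_w=[1, 1])

    def test_bias_feature_matches_plaintext(self, small_key):
        pk, sk = small_key
        cloud, hospital = _parties(small_key, seed=90)
        samples = [LabeledSample(x=(v,), label=1 if v >= 3 else -1) for v in range(1, 7)]
        cfg = TrainConfig(bias=True, iteration_max=200, seed=2)
        plain = train_plain(samples, cfg)
        enc = encrypt_samples(samples, pk, rng=random.Random(9))
        enc_model, _ = train_encrypted(cloud, hospital, enc, cfg)
        assert decrypt_model(enc_model, sk, pk).w == plain.w
        assert enc_model.converged


class TestMultiDisease:
    def test_independent_models_per_disease(self, small_key):
        pk, sk = small_key
        cloud, hospital = _parties(small_key, seed=100)
        rng = random.Random(10)
        all_enc = []
        plains = {}
        for k in (1, 2):
            train, _, _ = generate(SynthSpec(n_samples=20, d=3, seed=20 + k))
            train = [LabeledSample(x=s.x, label=s.label, disease_index=k) for s in train]
            plains[k] = train_plain(train, TrainConfig(seed=5))
            all_enc.extend(encrypt_samples(train, pk, rng=rng))
        models = train_all_diseases(cloud, hospital, all_enc, [1, 2], TrainConfig(seed=5))
        assert [m.disease_index for m in models] == [1, 2]
        for m in models:
            assert decrypt_model(m, sk, pk).w == plains[m.disease_index].w

    def test_empty_disease_index_warns_and_skips(self, small_key):
        pk, sk = small_key
        cloud, hospital = _parties(small_key, seed=110)
        enc = encrypt_samples(
            [LabeledSample(x=(1, 2), label=1, disease_index=1)], pk, rng=random.Random(11)
        )
        with pytest.warns(UserWarning, match="no samples"):
            models = train_all_diseases(cloud, hospital, enc, [1, 3], TrainConfig(seed=1))
        assert len(models) == 1


def test_model_encrypted_flag(small_key):
    pk, sk = small_key
    assert not Model(w=[1, 2]).encrypted
    from ppslp.paillier import encrypt

    assert Model(w=[encrypt(pk, 1)]).encrypted
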