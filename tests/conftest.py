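import math
import random

import pytest
import sympy

from ppslp.mpc import Party
from ppslp.paillier import PrivateKey, PublicKey


def make_key(prime_bits: int, seed: int) -> tuple[PublicKey, PrivateKey]:
    """Construct a key pair directly from sympy primes, bypassing keygen's
    minimum-size guard — small keys keep exact-arithmetic tests fast."""
    rng = random.Random(seed)
    while True:
        p = sympy.randprime(2 ** (prime_bits - 1), 2**prime_bits)
        q = sympy.randprime(2 ** (prime_bits - 1), 2**prime_bits)
        # randprime is deterministic per range; perturb via offset search
        q = sympy.nextprime(q + rng.randrange(0, 2 ** (prime_bits - 2)))
        if p != q and math.gcd(p * q, (p - 1) * (q - 1)) == 1:
            break
    n = p * q
    lam = math.lcm(p - 1, q - 1)
    g = n + 1
    mu = pow(((pow(g, lam, n * n) - 1) // n), -1, n)
    return PublicKey(n=n, g=g), PrivateKey(lam=lam, mu=mu, p=p, q=q)


@pytest.fixture(scope="session")
def toy_key() -> tuple[PublicKey, PrivateKey]:
    """The classic hand-checkable key: p=5, q=7, n=35, g=n+1=36."""
    p, q = 5, 7
    n = p * q
    lam = math.lcm(p - 1, q - 1)
    g = n + 1
    mu = pow((pow(g, lam, n * n) - 1) // n, -1, n)
    return PublicKey(n=n, g=g), PrivateKey(lam=lam, mu=mu, p=p, q=q)


@pytest.fixture(scope="session")
def small_key() -> tuple[PublicKey, PrivateKey]:
    """64-bit modulus: big enough for signed vector arithmetic, very fast."""
    return make_key(32, seed=5)


@pytest.fixture(scope="session")
def key256() -> tuple[PublicKey, PrivateKey]:
    """Working-size key (256-bit primes) shared by the heavier tests."""
    from ppslp.paillier import keygen

    return keygen(256, seed=11)


@pytest.fixture()
def parties(small_key):
    pk, sk = small_key
    return {
        "C1": Party("C1", pk=pk, seed=101),
        "C2": Party("C2", pk=pk, sk=sk, seed=102),
    }
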