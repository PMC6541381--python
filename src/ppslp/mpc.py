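"""Two-party computation plumbing: parties, messages, transcripts, counters.

Protocols in this package are executed in-process: "sending" a message
appends it to a shared :class:`Transcript`, and the receiving party's code
reads it from there.  No party object ever reaches into another's fields;
everything a party learns is either its own key material or a message
payload.  The Message/Transcript contract would let a networked backend
drop in without touching protocol logic.

The transcript also carries per-party :class:`~ppslp.paillier.OpLedger`
tallies (EXP/MUL/DIV on ciphertexts) and a round count, the two quantities
used for protocol cost accounting.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Any, Callable

from .paillier import Ciphertext, OpLedger, PrivateKey, PublicKey

__all__ = ["Party", "Message", "Transcript", "run_protocol", "op_counts"]


class ConfigurationError(RuntimeError):
    """A party lacks a key its role requires."""


@dataclass
class Party:
    """A protocol participant: a role label, keys, and a seeded RNG."""

    name: str
    pk: PublicKey | None = None
    sk: PrivateKey | None = None
    seed: int | None = None
    rng: random.Random = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rng = random.Random(self.seed) if self.seed is not None else random.Random()

    def require_pk(self) -> PublicKey:
        if self.pk is None:
            raise ConfigurationError(f"party {self.name!r} holds no public key")
        return self.pk

    def require_sk(self) -> PrivateKey:
        if self.sk is None:
            raise ConfigurationError(f"party {self.name!r} holds no private key")
        return self.sk


@dataclass
class Message:
    sender: str
    receiver: str
    payload: list[Any]
    tag: str


@dataclass
class Transcript:
    """Ordered message log plus per-party operation ledgers."""

    messages: list[Message] = field(default_factory=list)
    counters: dict[str, OpLedger] = field(default_factory=dict)

    def send(self, sender: str, receiver: str, payload: list[Any], tag: str) -> Message:
        msg = Message(sender=sender, receiver=receiver, payload=list(payload), tag=tag)
        self.messages.append(msg)
        return msg

    def ledger(self, party: str) -> OpLedger:
        return self.counters.setdefault(party, OpLedger())

    @property
    def rounds(self) -> int:
        """Number of request/response exchanges.

        Counted as direction alternations in the message sequence: a
        strictly alternating sequence of 2k messages is k rounds.
        """
        if not self.messages:
            return 0
        transitions = sum(
            1
            for a, b in zip(self.messages, self.messages[1:])
            if (a.sender, a.receiver) != (b.sender, b.receiver)
        )
        return (transitions + 1) // 2

    def to_jsonl(self) -> str:
        """One JSON line per message (ciphertexts hex-encoded), then a summary."""
        lines = []
        for m in self.messages:
            payload = [
                {"ciphertext": hex(p.value)} if isinstance(p, Ciphertext) else p
                for p in m.payload
            ]
            lines.append(
                json.dumps(
                    {"sender": m.sender, "receiver": m.receiver, "tag": m.tag, "payload": payload}
                )
            )
        lines.append(
            json.dumps(
                {
                    "summary": {
                        "rounds": self.rounds,
                        "counters": {p: led.as_dict() for p, led in self.counters.items()},
                    }
                }
            )
        )
        return "\n".join(lines) + "\n"


def run_protocol(
    protocol: Callable[..., Any], parties: dict[str, Party], **kwargs: Any
) -> tuple[Any, Transcript]:
    """Run a protocol callable against a fresh transcript.

    The protocol receives the party map, the transcript, and any extra
    keyword inputs, and returns its declared output.  Deterministic when
    every party's RNG is seeded.
    """
    transcript = Transcript()
    result = protocol(parties=parties, transcript=transcript, **kwargs)
    return result, transcript


def op_counts(t: Transcript, party: str) -> dict[str, int]:
    """EXP/MUL/DIV tallies a party accumulated during a protocol run."""
    if party not in t.counters:
        raise KeyError(f"no operations recorded for party {party!r}")
    return t.counters[party].as_dict()
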