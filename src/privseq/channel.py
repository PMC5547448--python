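"""In-process two-party message transport with an auditable transcript.

The researcher and the data owner exchange length-delimited byte strings over a
:class:`Channel`.  Every message is appended to an ordered transcript so tests
can assert leakage properties (e.g. that no plaintext shingle of the data owner
ever crosses the wire during the Diffie-Hellman PSI).  Delivery is FIFO per
direction; both parties run in one process, which is all the semi-honest
correctness arguments need — a TCP transport could be slotted in behind the
same interface.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

RESEARCHER = "researcher"
DATA_OWNER = "data_owner"
ROLES = (RESEARCHER, DATA_OWNER)


class ProtocolAbort(RuntimeError):
    """A two-party protocol stopped before completion.

    Carries the transcript position at which the abort happened so malformed
    messages can be located in audit logs.
    """

    def __init__(self, message: str, transcript_position: int | None = None):
        if transcript_position is not None:
            message = f"{message} (transcript position {transcript_position})"
        super().__init__(message)
        self.transcript_position = transcript_position


@dataclass
class Channel:
    """Ordered bidirectional byte transport between the two protocol roles."""

    transcript: list[tuple[str, bytes]] = field(default_factory=list)
    _queues: dict[str, deque] = field(
        default_factory=lambda: {r: deque() for r in ROLES}, repr=False
    )

    def send(self, sender: str, payload: bytes) -> None:
        if sender not in ROLES:
            raise ValueError(f"unknown role {sender!r}")
        if not isinstance(payload, (bytes, bytearray)):
            raise TypeError("channel payloads must be bytes")
        payload = bytes(payload)
        self.transcript.append((sender, payload))
        receiver = DATA_OWNER if sender == RESEARCHER else RESEARCHER
        self._queues[receiver].append(payload)

    def recv(self, receiver: str) -> bytes:
        if receiver not in ROLES:
            raise ValueError(f"unknown role {receiver!r}")
        queue = self._queues[receiver]
        if not queue:
            raise ProtocolAbort(
                f"{receiver} expected a message but none was pending",
                transcript_position=len(self.transcript),
            )
        return queue.popleft()

    def messages_from(self, sender: str) -> list[bytes]:
        return [p for s, p in self.transcript if s == sender]

    def dump_transcript(self, path) -> None:
        """Write the transcript as hex lines ``<sender>\\t<hex payload>`` for audits."""
        with open(path, "w", encoding="ascii") as fh:
            for sender, payload in self.transcript:
                fh.write(f"{sender}\t{payload.hex()}\n")
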