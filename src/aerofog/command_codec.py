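"""10-bit remote-operation command vector.

A command word carries eight payload flags (bits 0–7: irrigation,
recirculation, mixer, camera trigger, config write, config read, two
reserved), an attended-status bit (bit 8, set by the fog layer once the
request has been serviced) and an even-parity bit (bit 9) so that every
valid word has an even number of set bits. Single-bit transmission
corruption is therefore always detected; double-bit corruption is not
(plain parity cannot), and no error correction is attempted. Words
serialize as unsigned decimal integers for channel storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

__all__ = [
    "PAYLOAD_FIELDS",
    "CommandState",
    "ParityError",
    "encode",
    "decode",
    "mark_attended",
    "describe",
]

PAYLOAD_FIELDS = (
    "irrigation",
    "recirculation",
    "mixer",
    "camera_trigger",
    "config_write",
    "config_read",
    "reserved_a",
    "reserved_b",
)

_ATTENDED_BIT = 8
_PARITY_BIT = 9


class ParityError(ValueError):
    """Raised when a received word fails the even-parity check."""


@dataclass(frozen=True)
class CommandState:
    irrigation: bool = False
    recirculation: bool = False
    mixer: bool = False
    camera_trigger: bool = False
    config_write: bool = False
    config_read: bool = False
    reserved_a: bool = False
    reserved_b: bool = False
    attended: bool = False

    def payload_bits(self) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in PAYLOAD_FIELDS)


def encode(state: CommandState) -> int:
    """Encode a command state into a 10-bit word (0–1023).

    The parity bit is always computed here, never caller-supplied, so
    every encoded word has an even number of set bits.
    """
    word = 0
    for k, on in enumerate(state.payload_bits()):
        if on:
            word |= 1 << k
    if state.attended:
        word |= 1 << _ATTENDED_BIT
    if word.bit_count() % 2 == 1:
        word |= 1 << _PARITY_BIT
    return word


def decode(word: int) -> CommandState:
    """Decode a 10-bit word, verifying even parity.

    Raises :class:`ParityError` on a parity mismatch (signals a
    transmission error) and ``ValueError`` for out-of-range words.
    """
    if not (0 <= word <= 1023):
        raise ValueError(f"command word out of 10-bit range: {word}")
    if word.bit_count() % 2 == 1:
        raise ParityError(f"parity check failed for word {word}")
    kwargs = {name: bool(word >> k & 1) for k, name in enumerate(PAYLOAD_FIELDS)}
    return CommandState(attended=bool(word >> _ATTENDED_BIT & 1), **kwargs)


def mark_attended(word: int) -> int:
    """Set the attended bit of a valid word, recomputing parity.

    The payload is unchanged; marking an already-attended word is a
    no-op. Invalid (parity-violating) input raises :class:`ParityError`.
    """
    state = decode(word)
    if state.attended:
        return word
    return encode(
        CommandState(
            **{name: getattr(state, name) for name in PAYLOAD_FIELDS},
            attended=True,
        )
    )


def describe(word: int) -> str:
    """Human-readable decode used by the CLI."""
    state = decode(word)
    on = [name for name in PAYLOAD_FIELDS if getattr(state, name)]
    return (
        f"word {word} (0b{word:010b}): "
        f"payload={{{', '.join(on) if on else 'none'}}}, "
        f"attended={'yes' if state.attended else 'no'}, parity=ok"
    )
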