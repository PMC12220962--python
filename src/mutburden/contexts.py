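"""Canonical 96-channel trinucleotide substitution contexts.

Single-base substitutions are reported pyrimidine-centered: a mutation whose
reference base is a purine is reverse-complemented so that the middle base of
the trinucleotide is C or T. Channel order follows the COSMIC convention:
substitution classes C>A, C>G, C>T, T>A, T>C, T>G, and within each class the
5' then 3' flanks in alphabetical order (A, C, G, T).
"""

from __future__ import annotations

import re

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels, e.g. ``A[C>A]A``, in canonical order.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)

CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}

#: The 32 pyrimidine-centered trinucleotides (middle base C then T, flanks
#: alphabetical), the index space for genome-abundance weighting.
TRINUC_32 = tuple(
    f"{five}{mid}{three}" for mid in "CT" for five in _BASES for three in _BASES
)

TRINUC_INDEX = {t: i for i, t in enumerate(TRINUC_32)}

_CONTEXT_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def parse_context(context: str) -> tuple[str, str, str, str]:
    """Split a context label into (5' flank, ref, alt, 3' flank).

    Raises ``ValueError`` for anything that is not a well-formed
    ``X[R>A]Y`` label with R != A.
    """
    m = _CONTEXT_RE.match(context)
    if m is None:
        raise ValueError(f"malformed trinucleotide context: {context!r}")
    five, ref, alt, three = m.groups()
    if ref == alt:
        raise ValueError(f"context {context!r} has ref == alt")
    return five, ref, alt, three


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def collapse_context(context: str) -> str:
    """Return the pyrimidine-centered form of a context label.

    Purine-centered records are reverse-complemented (both flanks swap and
    complement, ref and alt complement). Already-collapsed labels are
    returned unchanged, so the map is idempotent.
    """
    five, ref, alt, three = parse_context(context)
    if ref in "CT":
        return f"{five}[{ref}>{alt}]{three}"
    return (
        f"{_COMPLEMENT[three]}[{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}]"
        f"{_COMPLEMENT[five]}"
    )


def channel_of(context: str) -> int:
    """Canonical channel index (0..95) of a context, collapsing if needed."""
    return CHANNEL_INDEX[collapse_context(context)]


def trinucleotide_of_channel(channel: int | str) -> str:
    """The pyrimidine-centered trinucleotide (e.g. ``ACG``) of a channel."""
    label = CHANNELS_96[channel] if isinstance(channel, int) else collapse_context(channel)
    five, ref, _, three = parse_context(label)
    return f"{five}{ref}{three}"
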