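"""Diagnosis-code handling: level-3 truncation, vocabularies, system mapping.

Diagnosis codes from different revisions of the ICD (or any coding system) are
kept as distinct tokens — a code is identified by the pair ``(system, code)``
and no semantic merging across systems is performed. Codes are reduced to the
three-character category level (e.g. ``C25.1`` → ``C25``), the granularity at
which the models operate.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

__all__ = ["truncate_code", "Vocabulary", "map_code_system", "PAD_TOKEN"]

PAD_TOKEN: tuple[str, str] = ("<pad>", "<pad>")

_PUNCT = re.compile(r"[^A-Za-z0-9]")


def truncate_code(raw_code: str, system: str = "icd10") -> str:
    """Reduce a diagnosis code to its three-character category.

    Punctuation (dots, dashes, whitespace) is stripped before truncation, so
    ``"C25.1"`` and ``"C251"`` both map to ``"C25"``. Codes with fewer than
    three significant characters are rejected.
    """
    if not raw_code:
        raise ValueError("empty diagnosis code")
    stripped = _PUNCT.sub("", raw_code)
    if len(stripped) < 3:
        raise ValueError(f"malformed diagnosis code {raw_code!r}: "
                         f"fewer than 3 significant characters")
    return stripped[:3].upper()


@dataclass
class Vocabulary:
    """Bijection between ``(system, code)`` tokens and contiguous indices.

    Index 0 is reserved for padding; real tokens start at 1. Token embeddings
    for the padding index are pinned to zero by the model, and the padding
    token is excluded from attribution aggregation.
    """

    token_to_index: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.token_to_index:
            self.token_to_index = {PAD_TOKEN: 0}
        self.index_to_token = {i: t for t, i in self.token_to_index.items()}

    @classmethod
    def build(cls, tokens) -> "Vocabulary":
        """Build from an iterable of (system, code) pairs, in first-seen order."""
        mapping = {PAD_TOKEN: 0}
        for tok in tokens:
            if tok not in mapping:
                mapping[tok] = len(mapping)
        return cls(mapping)

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def pad_index(self) -> int:
        return 0

    def encode(self, token: tuple[str, str]) -> int:
        try:
            return self.token_to_index[token]
        except KeyError:
            raise KeyError(f"token {token} not in vocabulary") from None

    def decode(self, index: int) -> tuple[str, str]:
        return self.index_to_token[index]

    def content_hash(self) -> str:
        """Stable hash of the token ordering, used to guard checkpoints."""
        h = hashlib.sha256()
        for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
            h.update(f"{idx}\t{tok[0]}\t{tok[1]}\n".encode())
        return h.hexdigest()[:16]


def map_code_system(events, mapping_table: dict[str, str], target_prefix: str = "D",
                    drop_unmapped: bool = True):
    """Translate events from one code system into another's vocabulary.

    Each event's level-3 code is looked up in ``mapping_table`` (e.g. an
    ICD-9 → ICD-10 general-equivalence table supplied by the caller; none is
    bundled), the mapped code is truncated to level 3, and ``target_prefix``
    is prepended — the convention used to align externally coded data with a
    registry whose ICD-10 codes carry a 'D' prefix.

    Returns ``(mapped_events, tally)`` where ``tally`` counts mapped vs
    unmapped tokens. Unmapped events are dropped when ``drop_unmapped`` is
    true, otherwise kept untranslated.
    """
    from .records import DiseaseEvent  # local import to avoid a cycle

    if not mapping_table:
        raise ValueError("empty mapping table")
    out = []
    tally = {"mapped": 0, "unmapped": 0}
    for ev in events:
        target = mapping_table.get(ev.code)
        if target is None:
            tally["unmapped"] += 1
            if not drop_unmapped:
                out.append(ev)
            continue
        tally["mapped"] += 1
        code = target_prefix + truncate_code(target)
        out.append(DiseaseEvent(code=code, date=ev.date, system="icd10"))
    return out, tally
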