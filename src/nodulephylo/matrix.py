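"""Discrete character matrices for parsimony analysis.

A :class:`CharacterMatrix` is a taxa x characters grid of small
non-negative integer states. SNV presence/absence yields binary
characters; binned copy-number profiles yield either paired binary
characters (amplified? deleted?) or a single ordered ternary character
per bin (loss < neutral < gain).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import ValidationError

#: the taxon label used for the all-ancestral outgroup row
ROOT_TAXON = "NORMAL"

_ALLOWED_STATES = {
    "binary": (0, 1),
    "ordered-ternary": (0, 1, 2),
}


@dataclass
class CharacterMatrix:
    taxa: list[str]
    characters: list[str]
    states: np.ndarray
    semantics: str = "binary"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValidationError("states must be a 2-D grid")
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValidationError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels")
        if self.semantics not in _ALLOWED_STATES:
            raise ValidationError(f"unknown state semantics {self.semantics!r}")
        lo, hi = min(_ALLOWED_STATES[self.semantics]), max(_ALLOWED_STATES[self.semantics])
        if self.states.size and (self.states.min() < lo or self.states.max() > hi):
            raise ValidationError(
                f"states outside {_ALLOWED_STATES[self.semantics]} for "
                f"{self.semantics} semantics"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def reorder(self, taxa: Sequence[str]) -> "CharacterMatrix":
        """Return a copy with rows ordered as ``taxa`` (a permutation)."""
        if sorted(taxa) != sorted(self.taxa):
            raise ValidationError("reorder taxa must be a permutation of existing taxa")
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), list(self.characters),
                               self.states[idx].copy(), self.semantics)

    def drop_constant(self) -> "CharacterMatrix":
        """Drop characters whose state is identical across all taxa."""
        if self.n_characters == 0:
            return self
        keep = ~(self.states == self.states[0]).all(axis=0)
        return CharacterMatrix(
            list(self.taxa),
            [c for c, k in zip(self.characters, keep) if k],
            self.states[:, keep].copy(),
            self.semantics,
        )

    def with_taxon(self, label: str, states: Sequence[int]) -> "CharacterMatrix":
        """Return a copy with one extra taxon row appended."""
        row = np.asarray(states, dtype=np.int64).reshape(1, -1)
        return CharacterMatrix(
            list(self.taxa) + [label],
            list(self.characters),
            np.vstack([self.states, row]) if self.n_characters else
            np.zeros((self.n_taxa + 1, 0), dtype=np.int64),
            self.semantics,
        )
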