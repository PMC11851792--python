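"""Synthetic phonetically balanced speech materials.

Clinical speech audiometry in French uses two open-set materials: 20
phonetically balanced "cochlear" word lists for testing in quiet and 5
logatom (meaningless pseudo-word) lists for testing in noise, each list
holding 17 words of 3 phonemes. The actual word lists are copyrighted
clinical material; the adaptive procedures and the scoring analyses depend
only on their *structure* (list count, words per list, phonemes per word,
vowel/consonant balance). This module therefore generates synthetic
materials with exactly that structure.

Words default to consonant-vowel-consonant, the shape of short French test
words, and phoneme balance is enforced across the whole material by quota
allocation: each class's slots are filled from a multiset of symbols whose
counts follow the inventory's target frequencies (largest-remainder
rounding), shuffled by the seed. Balance is quantified by
:func:`balance_divergence`, the total-variation distance between realized
and target phoneme frequencies.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import BLANK, UNKNOWN

__all__ = [
    "PhonemeInventory",
    "Word",
    "SpeechList",
    "SpeechMaterial",
    "GenerationError",
    "make_default_inventory",
    "generate_material",
    "balance_divergence",
    "phoneme_counts",
]

Kind = Literal["quiet", "noise"]

#: IPA-like symbol pools used for default inventories (French-flavoured).
VOWEL_POOL = ["a", "i", "u", "e", "o", "ɛ", "ɔ", "y", "ø", "œ", "ə", "ɑ̃", "ɛ̃", "ɔ̃"]
CONSONANT_POOL = [
    "p", "b", "t", "d", "k", "g", "f", "v", "s", "z",
    "ʃ", "ʒ", "m", "n", "ɲ", "l", "ʁ", "j", "w", "ɥ",
]

_RESERVED = {UNKNOWN, BLANK}


class GenerationError(RuntimeError):
    """Raised when the inventory cannot satisfy the generation constraints."""


@dataclass(frozen=True)
class PhonemeInventory:
    """Ordered phoneme set with vowel/consonant classes and target frequencies.

    ``target_freq`` must sum to 1 (within 1e-9); symbols must be unique,
    non-empty and distinct from the reserved scorer tokens.
    """

    symbols: tuple[str, ...]
    class_of: Mapping[str, str]
    target_freq: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("inventory symbols must be unique")
        for s in self.symbols:
            if not s:
                raise ValueError("inventory symbols must be non-empty")
            if s in _RESERVED:
                raise ValueError(f"symbol {s!r} is a reserved scorer token")
            if self.class_of.get(s) not in ("vowel", "consonant"):
                raise ValueError(f"symbol {s!r} has no vowel/consonant class")
        total = sum(self.target_freq[s] for s in self.symbols)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target frequencies sum to {total}, expected 1")

    @property
    def vowels(self) -> tuple[str, ...]:
        return tuple(s for s in self.symbols if self.class_of[s] == "vowel")

    @property
    def consonants(self) -> tuple[str, ...]:
        return tuple(s for s in self.symbols if self.class_of[s] == "consonant")

    def to_dict(self) -> dict:
        return {
            "symbols": list(self.symbols),
            "classes": {s: self.class_of[s] for s in self.symbols},
            "freqs": {s: self.target_freq[s] for s in self.symbols},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhonemeInventory":
        return cls(tuple(d["symbols"]), dict(d["classes"]), dict(d["freqs"]))


@dataclass(frozen=True)
class Word:
    label: str
    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.phonemes) < 1:
            raise ValueError("a word needs at least one phoneme")


@dataclass(frozen=True)
class SpeechList:
    list_id: str
    words: tuple[Word, ...]
    kind: Kind


@dataclass(frozen=True)
class SpeechMaterial:
    kind: Kind
    inventory: PhonemeInventory
    lists: tuple[SpeechList, ...]

    def __post_init__(self) -> None:
        ids = [sl.list_id for sl in self.lists]
        if len(set(ids)) != len(ids):
            raise ValueError("list_ids must be unique")
        symbols = set(self.inventory.symbols)
        for sl in self.lists:
            for w in sl.words:
                if not set(w.phonemes) <= symbols:
                    raise ValueError(
                        f"word {w.label!r} uses phonemes outside the inventory"
                    )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "inventory": self.inventory.to_dict(),
            "lists": [
                {
                    "list_id": sl.list_id,
                    "words": [
                        {"label": w.label, "phonemes": list(w.phonemes)}
                        for w in sl.words
                    ],
                }
                for sl in self.lists
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpeechMaterial":
        inv = PhonemeInventory.from_dict(d["inventory"])
        lists = tuple(
            SpeechList(
                sl["list_id"],
                tuple(Word(w["label"], tuple(w["phonemes"])) for w in sl["words"]),
                d["kind"],
            )
            for sl in d["lists"]
        )
        return cls(d["kind"], inv, lists)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SpeechMaterial":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def make_default_inventory(
    n_vowels: int,
    n_consonants: int,
    target_freq: Mapping[str, float] | None = None,
) -> PhonemeInventory:
    """Build an inventory of ``n_vowels`` + ``n_consonants`` symbols.

    Frequencies default to uniform over all symbols; pass ``target_freq``
    to override (must cover every symbol and sum to 1).
    """
    if n_vowels < 1 or n_consonants < 1:
        raise ValueError("need at least one vowel and one consonant")
    vowels = [
        VOWEL_POOL[i] if i < len(VOWEL_POOL) else f"V{i}" for i in range(n_vowels)
    ]
    consonants = [
        CONSONANT_POOL[i] if i < len(CONSONANT_POOL) else f"C{i}"
        for i in range(n_consonants)
    ]
    symbols = tuple(vowels + consonants)
    class_of = {s: "vowel" for s in vowels}
    class_of.update({s: "consonant" for s in consonants})
    if target_freq is None:
        target_freq = {s: 1.0 / len(symbols) for s in symbols}
    return PhonemeInventory(symbols, class_of, dict(target_freq))


def _vowel_positions(length: int) -> list[bool]:
    # CVC-style pattern: odd (0-based) positions are vowels; a 1-phoneme
    # word is a bare vowel. Guarantees >=1 vowel per word for length >= 1.
    if length == 1:
        return [True]
    return [i % 2 == 1 for i in range(length)]


def _quota_multiset(
    symbols: Sequence[str], weights: Sequence[float], n: int
) -> list[str]:
    """Largest-remainder allocation of ``n`` slots to ``symbols``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise GenerationError("class has zero total target frequency")
    quota = w / w.sum() * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - int(counts.sum())
    # stable tie-break: largest remainder first, then inventory order
    order = sorted(range(len(symbols)), key=lambda i: (-remainder[i], i))
    for i in order[:short]:
        counts[i] += 1
    out: list[str] = []
    for s, c in zip(symbols, counts):
        out.extend([s] * int(c))
    return out


def generate_material(
    kind: Kind,
    n_lists: int,
    words_per_list: int,
    phonemes_per_word: int,
    inventory: PhonemeInventory | None = None,
    seed: int = 0,
) -> SpeechMaterial:
    """Generate a phonetically balanced synthetic material.

    Deterministic under ``seed``: the same arguments always yield the same
    material, bit for bit.
    """
    if n_lists < 1 or words_per_list < 1 or phonemes_per_word < 1:
        raise ValueError("n_lists, words_per_list and phonemes_per_word must be >= 1")
    if kind not in ("quiet", "noise"):
        raise ValueError(f"unknown material kind {kind!r}")
    if inventory is None:
        inventory = make_default_inventory(6, 12)

    pattern = _vowel_positions(phonemes_per_word)
    n_words = n_lists * words_per_list
    n_vowel_slots = n_words * sum(pattern)
    n_consonant_slots = n_words * (len(pattern) - sum(pattern))
    if n_vowel_slots and not inventory.vowels:
        raise GenerationError("inventory has no vowels")
    if n_consonant_slots and not inventory.consonants:
        raise GenerationError("inventory has no consonants")

    rng = np.random.default_rng(seed)
    pools: dict[str, list[str]] = {}
    for cls, syms, n_slots in (
        ("vowel", inventory.vowels, n_vowel_slots),
        ("consonant", inventory.consonants, n_consonant_slots),
    ):
        if n_slots == 0:
            pools[cls] = []
            continue
        weights = [inventory.target_freq[s] for s in syms]
        pool = _quota_multiset(syms, weights, n_slots)
        rng.shuffle(pool)
        pools[cls] = pool

    lists = []
    for li in range(n_lists):
        words = []
        for _ in range(words_per_list):
            phonemes = tuple(
                pools["vowel"].pop() if is_vowel else pools["consonant"].pop()
                for is_vowel in pattern
            )
            words.append(Word("".join(phonemes), phonemes))
        lists.append(SpeechList(f"{kind}-{li + 1:02d}", tuple(words), kind))
    return SpeechMaterial(kind, inventory, tuple(lists))


def _realized_freq(material: SpeechMaterial) -> dict[str, float]:
    counts: Counter[str] = Counter()
    for sl in material.lists:
        for w in sl.words:
            counts.update(w.phonemes)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("material contains no phonemes")
    return {s: counts.get(s, 0) / total for s in material.inventory.symbols}


def balance_divergence(material: SpeechMaterial) -> float:
    """Total-variation distance between realized and target phoneme frequencies.

    0 means the material is perfectly balanced against the inventory's
    target; 1 is maximal imbalance.
    """
    realized = _realized_freq(material)
    target = material.inventory.target_freq
    return 0.5 * sum(
        abs(realized[s] - target[s]) for s in material.inventory.symbols
    )


def phoneme_counts(material: SpeechMaterial) -> pd.DataFrame:
    """Per-symbol phoneme counts and frequencies, for inspection/CSV export."""
    counts: Counter[str] = Counter()
    for sl in material.lists:
        for w in sl.words:
            counts.update(w.phonemes)
    total = sum(counts.values())
    inv = material.inventory
    return pd.DataFrame(
        {
            "symbol": list(inv.symbols),
            "class": [inv.class_of[s] for s in inv.symbols],
            "count": [counts.get(s, 0) for s in inv.symbols],
            "realized_freq": [counts.get(s, 0) / total for s in inv.symbols],
            "target_freq": [inv.target_freq[s] for s in inv.symbols],
        }
    )
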