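"""Variant representation, mutation sampling, and sequence encoding.

Positions are 1-based in all user-facing strings (``E27A`` mutates the
glutamate at position 27); internal array indices are 0-based and the
conversion happens only in parsers/formatters.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np

from ._aa import AA_ALPHABET, AA_INDEX, DESCRIPTOR_NAMES, descriptor_table

__all__ = [
    "Mutation",
    "Variant",
    "MutationSamplerConfig",
    "EncodedSequence",
    "MutationStringError",
    "WildTypeMismatchError",
    "DuplicatePositionError",
    "PositionOutOfRangeError",
    "parse_mutation_string",
    "format_mutation_string",
    "apply_mutations",
    "sample_variant",
    "sample_variants",
    "encode_sequence",
    "encode_variants",
    "default_channel_spec",
]


class MutationStringError(ValueError):
    """Base class for malformed or inconsistent mutation strings."""


class WildTypeMismatchError(MutationStringError):
    """Stated wild-type residue disagrees with the reference sequence."""


class DuplicatePositionError(MutationStringError):
    """The same position is mutated more than once."""


class PositionOutOfRangeError(MutationStringError):
    """Position lies outside the reference sequence."""


@dataclasses.dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution: 1-based ``position``, ``wt_aa`` -> ``mut_aa``."""

    position: int
    wt_aa: str
    mut_aa: str

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclasses.dataclass(frozen=True)
class Variant:
    """A protein variant: reference id, substitutions, and the full sequence."""

    wt_id: str
    mutations: tuple[Mutation, ...]
    sequence: str

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def __str__(self) -> str:
        return format_mutation_string(self)


def _validate_mutations(
    reference: str, mutations: Sequence[Mutation]
) -> tuple[Mutation, ...]:
    seen: set[int] = set()
    for m in mutations:
        if not (1 <= m.position <= len(reference)):
            raise PositionOutOfRangeError(
                f"position {m.position} outside reference of length {len(reference)}"
            )
        if m.position in seen:
            raise DuplicatePositionError(f"position {m.position} mutated twice")
        seen.add(m.position)
        if m.wt_aa != reference[m.position - 1]:
            raise WildTypeMismatchError(
                f"mutation {m}: reference has {reference[m.position - 1]} "
                f"at position {m.position}, not {m.wt_aa}"
            )
        if m.mut_aa == m.wt_aa:
            raise MutationStringError(f"mutation {m} is a no-op substitution")
        if m.mut_aa not in AA_INDEX:
            raise MutationStringError(f"mutation {m}: unknown amino acid {m.mut_aa!r}")
    return tuple(sorted(mutations))


def apply_mutations(
    reference: str, mutations: Iterable[Mutation], wt_id: str = "wt"
) -> Variant:
    """Build a validated :class:`Variant` from a reference and substitutions."""
    muts = _validate_mutations(reference, tuple(mutations))
    seq = list(reference)
    for m in muts:
        seq[m.position - 1] = m.mut_aa
    return Variant(wt_id=wt_id, mutations=muts, sequence="".join(seq))


def parse_mutation_string(
    s: str, reference: str, wt_id: str = "wt", sep: str = ","
) -> Variant:
    """Parse ``"E27A,K31D"``-style mutation strings against a reference.

    An empty (or all-whitespace) string denotes the wild type.
    """
    s = s.strip()
    if not s:
        return Variant(wt_id=wt_id, mutations=(), sequence=reference)
    mutations = []
    for token in s.split(sep):
        token = token.strip()
        if len(token) < 3 or not token[1:-1].isdigit():
            raise MutationStringError(f"malformed mutation token {token!r}")
        mutations.append(Mutation(int(token[1:-1]), token[0], token[-1]))
    return apply_mutations(reference, mutations, wt_id=wt_id)


def format_mutation_string(variant: Variant, sep: str = ",") -> str:
    """Inverse of :func:`parse_mutation_string` (sorted by position)."""
    return sep.join(str(m) for m in variant.mutations)


@dataclasses.dataclass(frozen=True)
class MutationSamplerConfig:
    """Uniform mutation sampling: mutation count in [min, max], positions
    drawn without replacement from non-excluded sites, substitutions uniform
    over the 19 non-wild-type amino acids."""

    min_mutations: int = 1
    max_mutations: int = 2
    excluded_positions: frozenset[int] = frozenset()

    def validate(self, reference: str) -> None:
        if self.min_mutations < 1 or self.max_mutations < self.min_mutations:
            raise ValueError("need 1 <= min_mutations <= max_mutations")
        bad = {p for p in self.excluded_positions if not 1 <= p <= len(reference)}
        if bad:
            raise ValueError(f"excluded positions outside reference: {sorted(bad)}")
        n_mutable = len(reference) - len(self.excluded_positions)
        if self.max_mutations > n_mutable:
            raise ValueError(
                f"max_mutations={self.max_mutations} exceeds {n_mutable} mutable sites"
            )


def sample_variant(
    reference: str,
    cfg: MutationSamplerConfig,
    rng: np.random.Generator,
    wt_id: str = "wt",
) -> Variant:
    """Draw one random variant under ``cfg`` from the given random stream."""
    cfg.validate(reference)
    mutable = [
        i for i in range(len(reference)) if (i + 1) not in cfg.excluded_positions
    ]
    bad = [i + 1 for i in mutable if reference[i] not in AA_INDEX]
    if bad:
        raise ValueError(
            f"reference has non-standard residues at mutable positions {bad}"
        )
    n_mut = int(rng.integers(cfg.min_mutations, cfg.max_mutations + 1))
    positions = rng.choice(len(mutable), size=n_mut, replace=False)
    mutations = []
    for idx in positions:
        pos = mutable[int(idx)] + 1
        wt = reference[pos - 1]
        alternatives = [aa for aa in AA_ALPHABET if aa != wt]
        mut = alternatives[int(rng.integers(19))]
        mutations.append(Mutation(pos, wt, mut))
    return apply_mutations(reference, mutations, wt_id=wt_id)


def sample_variants(
    reference: str,
    cfg: MutationSamplerConfig,
    n: int,
    rng: np.random.Generator,
    wt_id: str = "wt",
    unique: bool = True,
    max_tries_factor: int = 50,
) -> list[Variant]:
    """Draw ``n`` variants; with ``unique=True`` sequence-identical duplicates
    are rejected and redrawn (duplicates would waste simulated labels)."""
    out: list[Variant] = []
    seen: set[str] = set()
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries_factor * n:
            raise RuntimeError("could not draw enough unique variants")
        v = sample_variant(reference, cfg, rng, wt_id=wt_id)
        if unique:
            if v.sequence in seen:
                continue
            seen.add(v.sequence)
        out.append(v)
    return out


@dataclasses.dataclass(frozen=True)
class EncodedSequence:
    """Residues x channels encoding: 20 one-hot channels followed by
    standardized physicochemical descriptor channels."""

    matrix: np.ndarray
    channel_spec: tuple[str, ...]


def default_channel_spec() -> tuple[str, ...]:
    return tuple(f"onehot_{aa}" for aa in AA_ALPHABET) + tuple(DESCRIPTOR_NAMES)


def encode_sequence(
    sequence: str, channel_spec: tuple[str, ...] | None = None
) -> EncodedSequence:
    """Encode a sequence as a residues x channels matrix, N to C terminus."""
    spec = default_channel_spec() if channel_spec is None else tuple(channel_spec)
    if spec != default_channel_spec():
        raise ValueError("only the built-in channel spec is currently supported")
    table = descriptor_table()
    mat = np.zeros((len(sequence), 20 + table.shape[1]))
    for i, aa in enumerate(sequence):
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"unknown residue code {aa!r} at position {i + 1}")
        mat[i, j] = 1.0
        mat[i, 20:] = table[j]
    return EncodedSequence(matrix=mat, channel_spec=spec)


def encode_variants(
    variants: Sequence[Variant], channel_spec: tuple[str, ...] | None = None
) -> np.ndarray:
    """Stack encodings of many variants into an (n, L, C) array."""
    mats = [encode_sequence(v.sequence, channel_spec).matrix for v in variants]
    return np.stack(mats)
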