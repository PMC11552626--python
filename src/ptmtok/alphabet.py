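"""Token alphabet for modification-aware sequence encoding.

The alphabet covers the 20 canonical amino acids, ``-`` (no amino acid,
used for window padding beyond the protein termini), ``U`` (selenocysteine)
and up to two modification tokens, ``@`` and ``&``, which stand for residues
*known* to carry a modification.  Integer codes are fixed: ``-`` is 0, the
canonical amino acids in alphabetical order are 1..20 (``A``->1, ``C``->2,
``D``->3, ...), ``U`` is 21, and the modification tokens take the next
consecutive codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical amino acids, alphabetical, mapped to codes 1..20.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

PAD = "-"
SELENO = "U"
MOD_TOKENS = ("@", "&")

#: Ambiguity / rare codes normalized to the padding token in lenient mode.
NORMALIZE_TO_PAD = frozenset("XBZJO*")


class AlphabetError(ValueError):
    """Raised for token/alphabet configuration problems."""


@dataclass(frozen=True)
class LabelChannel:
    """One class of known modification sites.

    Parameters
    ----------
    modification_type:
        Name of the modification (e.g. ``"phospho-ST"``).
    residue_targets:
        Residue symbols eligible for this modification.
    sites:
        Mapping ``protein_id -> set of 1-based modified positions``.
    """

    modification_type: str
    residue_targets: frozenset[str]
    sites: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_targets", frozenset(self.residue_targets))
        object.__setattr__(
            self, "sites", {pid: frozenset(pos) for pid, pos in self.sites.items()}
        )

    def sites_for(self, protein_id: str) -> frozenset[int]:
        return self.sites.get(protein_id, frozenset())


@dataclass(frozen=True)
class ModAlphabet:
    """Token set and integer vocabulary, including modification tokens."""

    base_tokens: tuple[str, ...]
    mod_tokens: tuple[str, ...]
    #: (modification_type, residue) -> mod token
    mod_map: dict[tuple[str, str], str]
    index_of: dict[str, int]
    embedding_dim: int = 21

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.base_tokens + self.mod_tokens

    @property
    def vocab_size(self) -> int:
        return len(self.index_of)

    def token_for(self, mod_type: str, residue: str) -> str:
        try:
            return self.mod_map[(mod_type, residue)]
        except KeyError:
            raise AlphabetError(
                f"no modification token for ({mod_type!r}, {residue!r})"
            ) from None

    def residue_for_token(self, token: str) -> tuple[str, str]:
        """Invert ``mod_map`` for a mod token; error when ambiguous."""
        hits = [(mt, res) for (mt, res), tok in self.mod_map.items() if tok == token]
        if not hits:
            raise AlphabetError(f"{token!r} is not a modification token of this alphabet")
        if len(hits) > 1:
            raise AlphabetError(
                f"modification token {token!r} is ambiguous: maps to {sorted(hits)}"
            )
        return hits[0]

    def to_dict(self) -> dict:
        return {
            "base_tokens": list(self.base_tokens),
            "mod_tokens": list(self.mod_tokens),
            "mod_map": [[mt, res, tok] for (mt, res), tok in self.mod_map.items()],
            "embedding_dim": self.embedding_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModAlphabet":
        base = tuple(d["base_tokens"])
        mods = tuple(d["mod_tokens"])
        index_of = {tok: i for i, tok in enumerate(base + mods)}
        mod_map = {(mt, res): tok for mt, res, tok in d["mod_map"]}
        return cls(base, mods, mod_map, index_of, int(d["embedding_dim"]))


def build_alphabet(
    label_channels: list[LabelChannel] | None = None,
    *,
    per_residue_tokens: bool = True,
    embedding_dim: int = 21,
) -> ModAlphabet:
    """Build a :class:`ModAlphabet` for a set of label channels.

    With ``per_residue_tokens`` (default), a channel with two residue targets
    consumes one token per residue type (``@`` for the alphabetically first,
    ``&`` for the second); otherwise a channel uses a single token for all
    of its residues.  At most two modification tokens exist in total.
    """
    label_channels = label_channels or []
    base = (PAD,) + tuple(CANONICAL_AA) + (SELENO,)

    # (channel, residue-or-residue-class) pairs each needing a token
    needed: list[tuple[str, tuple[str, ...]]] = []
    for ch in label_channels:
        residues = tuple(sorted(ch.residue_targets))
        if not residues:
            raise AlphabetError(f"channel {ch.modification_type!r} has no residue targets")
        if per_residue_tokens:
            for res in residues:
                needed.append((ch.modification_type, (res,)))
        else:
            needed.append((ch.modification_type, residues))

    if len(needed) > len(MOD_TOKENS):
        offenders = sorted({mt for mt, _ in needed})
        raise AlphabetError(
            f"label channels {offenders} require {len(needed)} modification tokens; "
            f"at most {len(MOD_TOKENS)} ({'/'.join(MOD_TOKENS)}) are available"
        )

    mod_tokens = tuple(MOD_TOKENS[: len(needed)])
    mod_map: dict[tuple[str, str], str] = {}
    for tok, (mod_type, residues) in zip(mod_tokens, needed):
        for res in residues:
            mod_map[(mod_type, res)] = tok

    index_of = {tok: i for i, tok in enumerate(base + mod_tokens)}
    return ModAlphabet(base, mod_tokens, mod_map, index_of, embedding_dim)


def normalize_sequence(sequence: str, *, strict: bool = False) -> str:
    """Uppercase a residue string and map rare/ambiguity codes to ``-``.

    ``X``, ``B``, ``Z``, ``J``, ``O`` and ``*`` are replaced by the padding
    token with a logged warning; ``strict=True`` rejects them instead.
    """
    seq = sequence.upper()
    bad = sorted(set(seq) & NORMALIZE_TO_PAD)
    if bad:
        if strict:
            raise AlphabetError(f"non-standard residues {bad} in strict mode")
        logger.warning("normalizing non-standard residues %s to '-'", bad)
        seq = "".join(PAD if c in NORMALIZE_TO_PAD else c for c in seq)
    return seq


def apply_labels(
    sequence: str,
    channels: list[LabelChannel],
    alphabet: ModAlphabet,
    *,
    protein_id: str = "",
) -> str:
    """Replace each known-site residue by its modification token.

    ``sequence`` is the plain (unlabeled) residue string; sites are 1-based.
    Length is preserved and exactly the listed positions change.
    """
    out = list(sequence)
    for ch in channels:
        for pos in sorted(ch.sites_for(protein_id)):
            if not 1 <= pos <= len(sequence):
                raise AlphabetError(
                    f"site {protein_id or '<seq>'}:{pos} outside sequence of "
                    f"length {len(sequence)}"
                )
            res = sequence[pos - 1]
            if res not in ch.residue_targets:
                raise AlphabetError(
                    f"site {protein_id or '<seq>'}:{pos} is {res!r}, not one of the "
                    f"{ch.modification_type} targets {sorted(ch.residue_targets)}"
                )
            out[pos - 1] = alphabet.token_for(ch.modification_type, res)
    return "".join(out)


@dataclass(frozen=True)
class EncodedWindow:
    """Fixed-length window of tokens centered on a candidate site."""

    tokens: str
    codes: np.ndarray
    center_index: int  # 1-based; equals (k + 1) // 2
    origin: tuple[str, int]  # (protein id, 1-based center position)

    @property
    def k(self) -> int:
        return len(self.tokens)

    def __eq__(self, other: object) -> bool:  # codes is derived from tokens
        if not isinstance(other, EncodedWindow):
            return NotImplemented
        return self.tokens == other.tokens and self.origin == other.origin

    def __hash__(self) -> int:
        return hash((self.tokens, self.origin))


def vectorize(tokens: str, alphabet: ModAlphabet) -> np.ndarray:
    """Map a token string to its integer code vector."""
    try:
        return np.array([alphabet.index_of[t] for t in tokens], dtype=np.int64)
    except KeyError:
        for i, t in enumerate(tokens):
            if t not in alphabet.index_of:
                raise AlphabetError(
                    f"unknown token {t!r} at position {i + 1}"
                ) from None
        raise  # pragma: no cover

def devectorize(codes: np.ndarray, alphabet: ModAlphabet) -> str:
    """Inverse of :func:`vectorize`."""
    toks = alphabet.tokens
    out = []
    for i, c in enumerate(np.asarray(codes).tolist()):
        if not 0 <= c < len(toks):
            raise AlphabetError(f"code {c} at position {i + 1} outside vocabulary")
        out.append(toks[c])
    return "".join(out)


def extract_window(
    labeled_sequence: str,
    center: int,
    k: int,
    alphabet: ModAlphabet,
    *,
    center_residue: str | None = None,
    protein_id: str = "",
) -> EncodedWindow:
    """Extract the k-mer centered at ``center`` (1-based) with ``-`` padding.

    The center position is always emitted as the *unmodified* residue, even
    when it appears in a label channel: whether the center is modified is the
    prediction target, never an input.  If the labeled sequence carries a mod
    token at the center, the plain residue is recovered from ``center_residue``
    or, failing that, by inverting the alphabet's mod map.
    """
    if k % 2 == 0 or k < 1:
        raise AlphabetError(f"window length k must be odd and positive, got {k}")
    n = len(labeled_sequence)
    if not 1 <= center <= n:
        raise AlphabetError(f"center {center} outside sequence of length {n}")

    half = (k - 1) // 2
    chars = []
    for pos in range(center - half, center + half + 1):
        chars.append(labeled_sequence[pos - 1] if 1 <= pos <= n else PAD)

    mid = half  # 0-based center in the window
    if chars[mid] in alphabet.mod_tokens:
        if center_residue is not None:
            chars[mid] = center_residue
        else:
            _, chars[mid] = alphabet.residue_for_token(chars[mid])
    elif center_residue is not None and chars[mid] != center_residue:
        raise AlphabetError(
            f"center residue mismatch at {protein_id or '<seq>'}:{center}: "
            f"sequence has {chars[mid]!r}, expected {center_residue!r}"
        )

    tokens = "".join(chars)
    return EncodedWindow(
        tokens=tokens,
        codes=vectorize(tokens, alphabet),
        center_index=half + 1,
        origin=(protein_id, center),
    )
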