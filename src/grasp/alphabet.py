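"""Reduced amino-acid alphabets.

Many residues share physicochemical properties and can be merged into
equivalence classes without losing much homology signal; seeding in the
reduced space makes k-mer matches between diverged homologs far more
likely.  A reduced alphabet is a total map ``f`` from the 20 residues to
class-representative characters; ``X`` (ambiguity) is kept as its own
class so that X-containing k-mers never seed spuriously through class
merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import AMINO_ACIDS, SequenceError

#: Preset mapping files shipped with the package, keyed by preset name.
PRESETS = {"murphy10": "murphy10.tsv"}


@dataclass(frozen=True)
class ReducedAlphabet:
    """A total, idempotent mapping from residues to class representatives."""

    name: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = [a for a in AMINO_ACIDS if a not in self.mapping]
        if missing:
            raise SequenceError(
                f"alphabet {self.name!r} missing residues: {''.join(missing)}"
            )
        image = set(self.mapping[a] for a in AMINO_ACIDS)
        if len(image) >= 20:
            raise SequenceError(f"alphabet {self.name!r} is not reduced (|image| >= 20)")
        for a, rep in self.mapping.items():
            if self.mapping.get(rep, rep) != rep:
                raise SequenceError(
                    f"alphabet {self.name!r} is not idempotent: f({a})={rep}, "
                    f"f({rep})={self.mapping.get(rep)}"
                )
        # 'X' always maps to its own class
        object.__setattr__(self, "mapping", {**self.mapping, "X": self.mapping.get("X", "X")})
        object.__setattr__(self, "_table", str.maketrans(self.mapping))

    def reduce(self, m: str) -> str:
        """Apply the class substitution character-by-character."""
        for ch in m:
            if ch not in self.mapping:
                raise SequenceError(f"character {ch!r} outside alphabet {self.name!r}")
        return m.translate(self._table)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ReducedAlphabet":
        """Load a two-column (residue <TAB> representative) mapping file."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or len(parts[0]) != 1 or len(parts[1]) != 1:
                    raise SequenceError(f"malformed alphabet line: {line!r}")
                mapping[parts[0].upper()] = parts[1].upper()
        return cls(name or Path(path).stem, mapping)

    @classmethod
    def preset(cls, name: str) -> "ReducedAlphabet":
        """Load a named preset shipped with the package."""
        key = name.lower()
        if key not in PRESETS:
            raise SequenceError(
                f"unknown alphabet preset {name!r}; available: {sorted(PRESETS)}"
            )
        ref = resources.files("grasp.data").joinpath(PRESETS[key])
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, name=key)

    @classmethod
    def identity(cls) -> "ReducedAlphabet":
        """Degenerate mapping collapsing only I/L (useful in tests)."""
        mapping = {a: a for a in AMINO_ACIDS}
        mapping["I"] = "L"
        return cls("identity_il", mapping)


def reduce_sequence(m: str, alphabet: ReducedAlphabet) -> str:
    """Functional form of :meth:`ReducedAlphabet.reduce`."""
    return alphabet.reduce(m)


def load_alphabet(name_or_path: str) -> ReducedAlphabet:
    """Resolve a preset name or a mapping-file path."""
    if name_or_path.lower() in PRESETS:
        return ReducedAlphabet.preset(name_or_path)
    if Path(name_or_path).exists():
        return ReducedAlphabet.from_tsv(name_or_path)
    raise SequenceError(f"no such alphabet preset or file: {name_or_path!r}")
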