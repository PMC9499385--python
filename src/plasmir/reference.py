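"""Mature-on-hairpin miRNA reference.

A reference is a set of hairpin (precursor) sequences, each carrying one
mature miRNA at recorded coordinates. Coordinates are 0-based half-open on
the hairpin, so ``hairpin[start:end] == mature``. The hairpin context
flanking the mature ends is what decides whether an isomiR end-extension is
templated.

Interchange formats: mature FASTA + hairpin FASTA + a sidecar TSV with
columns (hairpin_id, mature_name, start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError, GenerationError

_DNA = set("ACGTN")


@dataclass(frozen=True)
class MatureRecord:
    """One mature miRNA anchored on its hairpin."""

    name: str
    sequence: str
    hairpin_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


@dataclass
class MiRNAReference:
    """Mature miRNAs with their precursor (hairpin) context.

    Invariants checked on construction: unique mature names, mature length
    in [16, 28], and ``hairpin[start:end] == mature_sequence``.
    """

    matures: list[MatureRecord]
    hairpins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [m.name for m in self.matures]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenerationError(f"duplicate mature miRNA names: {dupes}")
        for m in self.matures:
            if m.hairpin_id not in self.hairpins:
                raise ConfigurationError(f"{m.name}: unknown hairpin {m.hairpin_id!r}")
            hp = self.hairpins[m.hairpin_id]
            if not (0 <= m.start < m.end <= len(hp)):
                raise ConfigurationError(f"{m.name}: coordinates outside hairpin")
            if hp[m.start : m.end] != m.sequence:
                raise ConfigurationError(f"{m.name}: mature sequence disagrees with hairpin slice")
            if not 16 <= len(m.sequence) <= 28:
                raise ConfigurationError(f"{m.name}: mature length {len(m.sequence)} outside [16, 28]")
            if not set(m.sequence) <= _DNA:
                raise ConfigurationError(f"{m.name}: non-ACGTN characters in mature sequence")
        self._by_name = {m.name: m for m in self.matures}

    def __len__(self) -> int:
        return len(self.matures)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> MatureRecord:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.matures]

    def hairpin_of(self, name: str) -> str:
        return self.hairpins[self._by_name[name].hairpin_id]

    # ------------------------------------------------------------------ I/O

    def write(self, outdir: str | Path) -> None:
        """Write mature.fa, hairpin.fa and coordinates.tsv into *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "mature.fa", "w") as fh:
            for m in self.matures:
                fh.write(f">{m.name}\n{m.sequence}\n")
        with open(outdir / "hairpin.fa", "w") as fh:
            for hid in sorted(self.hairpins):
                fh.write(f">{hid}\n{self.hairpins[hid]}\n")
        with open(outdir / "coordinates.tsv", "w") as fh:
            fh.write("hairpin_id\tmature_name\tstart\tend\n")
            for m in self.matures:
                fh.write(f"{m.hairpin_id}\t{m.name}\t{m.start}\t{m.end}\n")

    @classmethod
    def read(cls, refdir: str | Path) -> "MiRNAReference":
        refdir = Path(refdir)
        hairpins = dict(_read_fasta(refdir / "hairpin.fa"))
        matures = []
        with open(refdir / "coordinates.tsv") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                hid, name = f[idx["hairpin_id"]], f[idx["mature_name"]]
                start, end = int(f[idx["start"]]), int(f[idx["end"]])
                matures.append(
                    MatureRecord(name=name, sequence=hairpins[hid][start:end], hairpin_id=hid, start=start, end=end)
                )
        return cls(matures=matures, hairpins=hairpins)


def _read_fasta(path: str | Path) -> Iterable[tuple[str, str]]:
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)
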