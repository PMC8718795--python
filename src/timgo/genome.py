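"""Genome sequence access and small DNA utilities."""

from __future__ import annotations

from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC core alphabet + N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Uppercase, 1-based-inclusive access over contigs.

    Wraps either an indexed FASTA (via pyfaidx) or a plain dict of contig
    name -> sequence string (handy in tests).
    """

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._contigs

    def contig_length(self, chrom: str) -> int:
        return len(self._seq(chrom))

    def _seq(self, chrom: str) -> str:
        try:
            return self._contigs[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not present in genome") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases ``start..end`` 1-based inclusive, clipped to the contig."""
        seq = self._seq(chrom)
        if end < start:
            return ""
        return seq[max(start - 1, 0) : min(end, len(seq))]

    def names(self) -> list[str]:
        return list(self._contigs)


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
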