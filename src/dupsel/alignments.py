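"""In-frame codon alignments over the 61 sense codons.

Sequences are stored as integer codon codes (0..60 in TCAG order, matching
the codeml convention); codons containing gaps/ambiguities and stop codons
become MISSING (-1) with a logged warning for stops.  An optional boolean
column mask marks codon columns that were trimmed out of the alignment.
"""

from __future__ import annotations

import io
import itertools
import logging
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

__all__ = ["CODONS", "CODON_INDEX", "AMINO_ACIDS", "MISSING", "CodonAlignment", "read_codon_alignment"]

_STANDARD = unambiguous_dna_by_id[1]
_BASES = "TCAG"

#: the 61 sense codons of the standard nuclear code, TCAG-lexicographic
CODONS: list[str] = [
    "".join(p)
    for p in itertools.product(_BASES, repeat=3)
    if "".join(p) not in _STANDARD.stop_codons
]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS: list[str] = [_STANDARD.forward_table[c] for c in CODONS]
STOP_CODONS = set(_STANDARD.stop_codons)
MISSING = -1


class CodonAlignment:
    """Codon alignment: names, (n_seq, n_sites) int codes, optional mask.

    ``mask[j]`` is True when codon column ``j`` was trimmed.  Columns and
    protein residues are 1-based inclusive in all user-facing interfaces,
    with residue i corresponding to codon column i.
    """

    def __init__(self, names: Sequence[str], codes: np.ndarray, mask: np.ndarray | None = None):
        self.names = list(names)
        self.codes = np.asarray(codes, dtype=np.int16)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.names):
            raise ValueError("codes must be (n_seq, n_sites) matching names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        if mask is None:
            mask = np.zeros(self.codes.shape[1], dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != (self.codes.shape[1],):
            raise ValueError("mask length must equal the number of codon columns")

    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(
        cls,
        seqs: Mapping[str, str] | Iterable[tuple[str, str]],
        mask_columns: Iterable[int] | None = None,
    ) -> "CodonAlignment":
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        names = [nm for nm, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned (equal length)")
        (nt_len,) = lengths
        if nt_len % 3 != 0:
            raise ValueError(f"alignment length {nt_len} is not divisible by 3")
        n_sites = nt_len // 3
        codes = np.full((len(items), n_sites), MISSING, dtype=np.int16)
        n_stop = 0
        for i, (_, seq) in enumerate(items):
            s = seq.upper().replace("U", "T")
            for j in range(n_sites):
                codon = s[3 * j : 3 * j + 3]
                k = CODON_INDEX.get(codon)
                if k is not None:
                    codes[i, j] = k
                elif codon in STOP_CODONS:
                    n_stop += 1
        if n_stop:
            logger.warning("%d stop codon(s) treated as missing data", n_stop)
        mask = np.zeros(n_sites, dtype=bool)
        if mask_columns is not None:
            cols = np.asarray(list(mask_columns), dtype=int)
            if cols.size and (cols.min() < 1 or cols.max() > n_sites):
                raise ValueError("mask columns out of range (1-based codon columns)")
            mask[cols - 1] = True
        return cls(names, codes, mask)

    @classmethod
    def from_fasta(cls, source, mask_columns: Iterable[int] | None = None) -> "CodonAlignment":
        handle = _as_handle(source)
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
        if not records:
            raise ValueError("no sequences found in FASTA input")
        return cls.from_sequences(records, mask_columns)

    def to_fasta(self) -> str:
        out = []
        for i, nm in enumerate(self.names):
            seq = "".join(CODONS[c] if c >= 0 else "---" for c in self.codes[i])
            out.append(f">{nm}\n{seq}")
        return "\n".join(out) + "\n"

    def n_missing(self) -> int:
        return int((self.codes == MISSING).sum())

    def codon_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        """Empirical frequencies over the 61 sense codons (F61 input)."""
        counts = np.bincount(self.codes[self.codes >= 0].ravel(), minlength=61).astype(float)
        counts += pseudocount
        return counts / counts.sum()

    def f3x4_frequencies(self) -> np.ndarray:
        """F3x4 codon frequencies from position-specific nucleotide counts."""
        pos_counts = np.zeros((3, 4))  # TCAG
        base_idx = {b: k for k, b in enumerate(_BASES)}
        obs = self.codes[self.codes >= 0]
        for code in np.bincount(obs.ravel(), minlength=61).nonzero()[0]:
            n = (self.codes == code).sum()
            for pos, b in enumerate(CODONS[code]):
                pos_counts[pos, base_idx[b]] += n
        pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos_freq[0, base_idx[c[0]]] * pos_freq[1, base_idx[c[1]]] * pos_freq[2, base_idx[c[2]]]
                for c in CODONS
            ]
        )
        if np.any(pi <= 0):
            pi += 1e-8
        return pi / pi.sum()


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    text = str(source)
    if text.lstrip().startswith(">"):
        return io.StringIO(text)
    if os.path.exists(text):
        return open(text)
    raise ValueError("source must be FASTA text, a path, or a file handle")


def read_codon_alignment(source, mask: Iterable[int] | str | None = None) -> CodonAlignment:
    """Read an in-frame codon alignment from FASTA.

    ``mask`` may be an iterable of 1-based codon column indices or a path
    to a text file with one column index per line.
    """
    cols = None
    if mask is not None:
        if isinstance(mask, (str, os.PathLike)) and os.path.exists(str(mask)):
            with open(mask) as fh:
                cols = [int(line) for line in fh if line.strip()]
        else:
            cols = list(mask)
    return CodonAlignment.from_fasta(source, cols)
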