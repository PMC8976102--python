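"""Mitogenome annotation data model and feature statistics.

A vertebrate mitogenome is a ~16.5-kb circular molecule carrying a canonical
complement of 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one control
region (D-loop).  Deviation from that complement is worth flagging: it
usually indicates a truncated or mis-annotated record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq

CANONICAL_COMPLEMENT = {"CDS": 13, "tRNA": 22, "rRNA": 2, "D-loop": 1}


@dataclass
class MitoGenome:
    """A (circular) mitogenome sequence with annotated feature intervals.

    Features are ``(name, kind, start, end)`` tuples, 0-based half-open;
    on a circular molecule ``end`` may exceed the sequence length, meaning
    the feature wraps past the origin.
    """

    name: str
    seq: np.ndarray              # uint8 base codes
    features: list[tuple[str, str, int, int]] = field(default_factory=list)
    circular: bool = True

    def __len__(self) -> int:
        return int(self.seq.size)

    def sequence(self) -> str:
        return _seq.decode(self.seq)

    def gc_content(self) -> float:
        return _seq.gc_fraction(self.seq)

    def feature_sequence(self, name: str) -> str:
        for fname, _kind, start, end in self.features:
            if fname == name:
                if end <= len(self):
                    return _seq.decode(self.seq[start:end])
                if not self.circular:
                    raise ValueError(f"feature {name} overruns a linear record")
                return _seq.decode(np.concatenate(
                    [self.seq[start:], self.seq[: end - len(self)]]))
        raise KeyError(name)

    def rotate(self, origin: int) -> "MitoGenome":
        """Move the sequence origin of a circular record to ``origin``."""
        if not self.circular:
            raise ValueError("cannot rotate a linear record")
        L = len(self)
        origin %= L
        seq = np.concatenate([self.seq[origin:], self.seq[:origin]])
        feats = []
        for fname, kind, start, end in self.features:
            ns = (start - origin) % L
            feats.append((fname, kind, ns, ns + (end - start)))
        return MitoGenome(self.name, seq, feats, circular=True)

    def linearized_at_first_cds(self) -> "MitoGenome":
        """Canonical rotation used before alignment: origin at the first CDS."""
        starts = [s for _n, k, s, _e in self.features if k == "CDS"]
        return self.rotate(min(starts)) if starts else self


def mito_feature_counts(record: MitoGenome) -> dict:
    """Count features by kind and flag deviation from the canonical
    vertebrate complement (13 CDS / 22 tRNA / 2 rRNA / 1 D-loop)."""
    counts: dict[str, int] = {}
    for _name, kind, _s, _e in record.features:
        counts[kind] = counts.get(kind, 0) + 1
    deviates = any(counts.get(k, 0) != v for k, v in CANONICAL_COMPLEMENT.items())
    return {"counts": counts, "canonical": not deviates}
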