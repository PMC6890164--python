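"""Shared helpers for the test suite."""

import numpy as np

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def brute_force_circular_sites(seq: str, motif: str) -> list[int]:
    """Independent oracle: scan every rotation of the circular sequence."""
    n = len(seq)
    hits = set()
    for rot in range(n):
        rotated = seq[rot:] + seq[:rot]
        if rotated.startswith(motif):
            hits.add(rot)
    return sorted(hits)


def brute_force_linear_sites(seq: str, motif: str) -> list[int]:
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]
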