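"""Synthetic splice-site-like dataset generator.

Balanced binary datasets of fixed-length DNA windows: true sequences carry a
canonical dimer (GT donor-like / AG acceptor-like) at a fixed offset, with
flanking positions optionally drawn from a peaked consensus profile; false
sequences are background draws.  Difficulty is tuned by ``decoy_rate`` (the
fraction of false sequences that carry the bare dimer at the site offset —
without the consensus flanks) and by the sharpness of the consensus.

Probability rows follow the encoding channel order A, T, C, G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import ALPHABET, DNASequence

_UNIFORM = np.full(4, 0.25)


def _check_rows(rows, what):
    rows = np.asarray(rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[1] != 4:
        raise ValueError(f"{what}: probability rows must have 4 columns (A,T,C,G)")
    if np.any(rows < 0) or np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{what}: rows must be probability vectors summing to 1")
    return rows


@dataclass
class MotifModel:
    """Planted-motif model for true splice-site-like sequences.

    ``site_offset`` is the 0-based index of the dimer's first base.
    ``upstream``/``downstream`` are optional consensus probability rows for
    the positions immediately before/after the dimer; everything else is
    drawn from ``background``.
    """

    dimer: str = "GT"
    site_offset: int = 70
    upstream: np.ndarray | None = None
    downstream: np.ndarray | None = None
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())

    def __post_init__(self):
        self.dimer = self.dimer.upper()
        if len(self.dimer) != 2 or any(b not in ALPHABET for b in self.dimer):
            raise ValueError(f"dimer must be a 2-mer over {ALPHABET}, got {self.dimer!r}")
        if self.site_offset < 0:
            raise ValueError("site_offset must be >= 0")
        self.background = _check_rows(self.background, "background")[0]
        if self.upstream is not None:
            self.upstream = _check_rows(self.upstream, "upstream")
        if self.downstream is not None:
            self.downstream = _check_rows(self.downstream, "downstream")

    @property
    def flank_up(self) -> int:
        return 0 if self.upstream is None else len(self.upstream)

    @property
    def flank_down(self) -> int:
        return 0 if self.downstream is None else len(self.downstream)

    def check_fits(self, length: int) -> None:
        if self.site_offset + 2 > length:
            raise ValueError(
                f"dimer at offset {self.site_offset} does not fit in length {length}"
            )
        if self.site_offset - self.flank_up < 0 or self.site_offset + 2 + self.flank_down > length:
            raise ValueError("consensus flanks do not fit in the sequence length")


def consensus_profile(favored: str, sharpness: float = 0.88) -> np.ndarray:
    """Probability rows putting ``sharpness`` mass on each favored base."""
    if not 0.25 <= sharpness <= 1.0:
        raise ValueError("sharpness must be in [0.25, 1]")
    rows = np.full((len(favored), 4), (1.0 - sharpness) / 3.0)
    for i, base in enumerate(favored.upper()):
        rows[i, ALPHABET.index(base)] = sharpness
    return rows


def default_motif(length: int, dimer: str = "GT", site_offset: int | None = None,
                  flank: int = 5, sharpness: float = 0.88) -> MotifModel:
    """Donor/acceptor-like default: the dimer sits at offset 70 of a 141-mer
    (roughly centered for other lengths) inside a peaked consensus context,
    so the full motif is rare under uniform background."""
    if site_offset is None:
        site_offset = 70 if length == 141 else max((length - 2) // 2, 0)
    flank = min(flank, site_offset, max(length - site_offset - 2, 0))
    up = down = None
    if flank > 0:
        context = ("AGGTAAGTCA" * 3)  # fixed, arbitrary favored-base pattern
        up = consensus_profile(context[:flank], sharpness)
        down = consensus_profile(context[flank : 2 * flank], sharpness)
    return MotifModel(dimer=dimer, site_offset=site_offset, upstream=up, downstream=down)


@dataclass
class SyntheticConfig:
    """Generator settings: ``n`` total sequences (balanced classes) of a
    fixed ``length``; ``decoy_rate`` controls how often false sequences carry
    the bare dimer at the site offset."""

    n: int = 2000
    length: int = 141
    motif: MotifModel | None = None
    decoy_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0 or self.n % 2 != 0:
            raise ValueError(f"n must be a positive even number, got {self.n}")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must be in [0, 1]")
        if self.motif is None:
            self.motif = default_motif(self.length)
        self.motif.check_fits(self.length)


def _draw(rng, rows):
    """Sample one base index per probability row."""
    u = rng.random(len(rows))
    return (np.cumsum(rows, axis=1) < u[:, None]).sum(axis=1)


def generate_splice_dataset(config: SyntheticConfig) -> list[DNASequence]:
    """Generate ``n/2`` true and ``n/2`` false sequences, fully seeded.

    True sequences: background draw, then the consensus flanks and the exact
    dimer are planted at the site.  False sequences: background draw; a
    ``decoy_rate`` Bernoulli fraction gets the bare dimer planted at the
    site, the rest are guaranteed not to carry it there.
    """
    m = config.motif
    rng = np.random.default_rng(config.seed)
    half = config.n // 2
    bg_rows = np.broadcast_to(m.background, (config.length, 4))
    dimer_idx = [ALPHABET.index(b) for b in m.dimer]
    out = []

    for i in range(half):
        idx = _draw(rng, bg_rows)
        if m.upstream is not None:
            idx[m.site_offset - m.flank_up : m.site_offset] = _draw(rng, m.upstream)
        idx[m.site_offset : m.site_offset + 2] = dimer_idx
        if m.downstream is not None:
            idx[m.site_offset + 2 : m.site_offset + 2 + m.flank_down] = _draw(rng, m.downstream)
        out.append(DNASequence(id=f"pos_{i}", bases="".join(ALPHABET[j] for j in idx), label=1))

    for i in range(half):
        idx = _draw(rng, bg_rows)
        if rng.random() < config.decoy_rate:
            idx[m.site_offset : m.site_offset + 2] = dimer_idx
        else:
            while list(idx[m.site_offset : m.site_offset + 2]) == dimer_idx:
                idx[m.site_offset : m.site_offset + 2] = _draw(rng, bg_rows[:2])
        out.append(DNASequence(id=f"neg_{i}", bases="".join(ALPHABET[j] for j in idx), label=0))
    return out


# ---------------------------------------------------------------------------
# writers (seqdata dialects)
# ---------------------------------------------------------------------------


def write_tsv(seqs: list[DNASequence], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for s in seqs:
            fh.write(f"{s.bases}\t{s.label}\n")


def write_fasta(seqs: list[DNASequence], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for s in seqs:
            fh.write(f">{s.id} label={s.label}\n{s.bases}\n")
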