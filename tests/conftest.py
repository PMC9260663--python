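from __future__ import annotations

import numpy as np
import pytest

from oredit.io_formats import AlignedRead, GeneModel, Genome


def make_read(
    position: int,
    sequence: str,
    read_id: str = "r",
    contig: str = "chrM",
    qualities: tuple[int, ...] | None = None,
    mapping_quality: int = 60,
    is_duplicate: bool = False,
    cigar: str | None = None,
) -> AlignedRead:
    return AlignedRead(
        read_id=read_id,
        contig=contig,
        position=position,
        cigar=cigar or f"{len(sequence)}M",
        sequence=sequence,
        qualities=qualities or tuple([40] * len(sequence)),
        mapping_quality=mapping_quality,
        is_duplicate=is_duplicate,
    )


def reads_at(
    genome: Genome,
    position: int,
    n_ref: int,
    n_alt: int,
    alt: str,
    length: int = 20,
    **kwargs,
) -> list[AlignedRead]:
    """Reads covering ``position``: n_ref matching the reference everywhere,
    n_alt carrying ``alt`` at the position."""
    start = max(1, min(position - length // 2, len(genome) - length + 1))
    template = genome.sequence[start - 1 : start - 1 + length]
    offset = position - start
    out = []
    for i in range(n_ref):
        out.append(make_read(start, template, read_id=f"ref{position}_{i}", **kwargs))
    mutated = template[:offset] + alt + template[offset + 1 :]
    for i in range(n_alt):
        out.append(make_read(start, mutated, read_id=f"alt{position}_{i}", **kwargs))
    return out


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return Genome(name="chrM", sequence=seq)


@pytest.fixture
def toy_gene_models() -> list[GeneModel]:
    """Two single-part genes on opposite strands plus a two-part CDS."""
    models = []
    for gid, start, end, strand in [
        ("gplus", 51, 110, "+"),
        ("gminus", 201, 260, "-"),
    ]:
        models.append(GeneModel(gid, "chrM", start, end, strand, "gene"))
        models.append(GeneModel(gid, "chrM", start, end, strand, "CDS"))
    models.append(GeneModel("gsplit", "chrM", 301, 340, "+", "gene"))
    models.append(GeneModel("gsplit", "chrM", 301, 318, "+", "CDS"))
    models.append(GeneModel("gsplit", "chrM", 325, 336, "+", "CDS"))
    return models
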