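import numpy as np
import pytest

from ssrphylo.datasets import CHLOROPLAST, MISSING, NUCLEAR, GenotypeDataset, Locus


def make_dataset(pop_genotypes: dict[str, list[list[tuple]]],
                 loci: list[Locus]) -> GenotypeDataset:
    """Build a dataset from {pop: [per-individual list of per-locus calls]}.

    A diploid call is a 2-tuple of allele codes, a haploid call a 1-tuple or
    int; None means missing.
    """
    pop_ids = list(pop_genotypes)
    individuals, pop_index, rows = [], [], []
    for k, (pop, inds) in enumerate(pop_genotypes.items()):
        for i, calls in enumerate(inds):
            individuals.append(f"{pop}_{i + 1}")
            pop_index.append(k)
            row = np.zeros((len(loci), 2), dtype=int)
            for j, call in enumerate(calls):
                if call is None:
                    continue
                if isinstance(call, int):
                    call = (call,)
                row[j, 0] = call[0]
                if len(call) > 1:
                    row[j, 1] = call[1]
            rows.append(row)
    return GenotypeDataset(loci=loci, pop_ids=pop_ids, individuals=individuals,
                           pop_index=np.array(pop_index), alleles=np.stack(rows))


@pytest.fixture
def two_pop_dataset():
    """Two populations, two nuclear loci and one chloroplast locus."""
    loci = [Locus("nuA", NUCLEAR, 2), Locus("nuB", NUCLEAR, 2),
            Locus("cpA", CHLOROPLAST, 1)]
    return make_dataset({
        "p1": [[(100, 102), (140, 140), (7,)],
               [(100, 100), (140, 146), (7,)],
               [(102, 104), (146, 146), (8,)]],
        "p2": [[(104, 104), (140, 146), (8,)],
               [(100, 104), (146, 146), (8,)],
               [(102, 102), (140, 140), (9,)]],
    }, loci)
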