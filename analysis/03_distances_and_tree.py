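#!/usr/bin/env python
"""Pairwise distances between haplotypes and the NJ gene tree.

Computes the uncorrected (count) and Kimura 2-parameter distance matrices
over the haplotypes plus the trusted reference, writes them as
lower-triangular TSVs (and a PHYLIP matrix), builds the neighbor-joining
tree on K2P distances, and checks whether the haplotypes diverging from the
reference form their own exclusive cluster.
"""

from pathlib import Path

from numtscan import (
    collapse_haplotypes,
    distance_matrix,
    is_exclusive_cluster,
    nj_tree,
    read_alignment,
    trim_alignment,
)
from numtscan.alignio import AlignedRecord, AlignedSeqSet
from numtscan.simulate import REFERENCE_ID

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fasta = RESULTS / "sim_cytb.fasta"
    ref_fasta = RESULTS / "sim_reference.fasta"
    if not fasta.exists() or not ref_fasta.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    aln = trim_alignment(read_alignment(fasta))
    refs = read_alignment(ref_fasta, site_parser=None)
    haps = collapse_haplotypes(aln)

    recs = tuple(AlignedRecord(h.hap_id, h.seq) for h in haps) + refs.records
    hap_aln = AlignedSeqSet(records=recs)

    dm_counts = distance_matrix(hap_aln, "ndiff")
    dm_k2p = distance_matrix(hap_aln, "k2p")
    dm_counts.to_tsv(RESULTS / "distances_counts.tsv")
    dm_k2p.to_tsv(RESULTS / "distances_k2p.tsv")
    dm_k2p.to_phylip(RESULTS / "distances_k2p.phy")

    print("pairwise divergences (variable sites | K2P):")
    labels = dm_k2p.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            print(f"  {labels[i]} vs {labels[j]}: "
                  f"{int(dm_counts.values[i, j])} sites | "
                  f"K2P {dm_k2p.values[i, j]:.3f}")

    if len(labels) >= 3:
        tree = nj_tree(dm_k2p)
        tree.write(path=str(RESULTS / "gene_tree.nwk"), schema="newick")
        print(f"NJ tree written to {RESULTS / 'gene_tree.nwk'}")
        divergent = [
            lab for lab in labels
            if lab != REFERENCE_ID and dm_k2p.get(lab, REFERENCE_ID)
            >= 1.5 * min(dm_k2p.get(x, REFERENCE_ID) for x in labels if x != REFERENCE_ID)
        ]
        if 2 <= len(divergent) < len(labels) - 1:
            sep = is_exclusive_cluster(tree, divergent, REFERENCE_ID)
            print(f"divergent haplotypes {divergent} exclusive vs reference: {sep}")
    print(f"wrote distance tables under {RESULTS}")


if __name__ == "__main__":
    main()
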