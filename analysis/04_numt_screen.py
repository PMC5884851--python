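#!/usr/bin/env python
"""Screen every haplotype against the trusted reference and call verdicts.

Runs the full decision procedure — ORF screen, GC content, codon-position
substitution profiles against the mtDNA expectation intervals — and compares
the calls with the simulation's truth labels. Also cross-compares the
flagged haplotypes with each other, the pseudogene-vs-pseudogene evidence.
"""

import csv
from pathlib import Path

from numtscan import (
    PUTATIVE_NUMT,
    ScreenConfig,
    collapse_haplotypes,
    cross_compare,
    read_alignment,
    screen_dataset,
    trim_alignment,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fasta = RESULTS / "sim_cytb.fasta"
    ref_fasta = RESULTS / "sim_reference.fasta"
    if not fasta.exists() or not ref_fasta.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    aln = trim_alignment(read_alignment(fasta))
    refs = read_alignment(ref_fasta, site_parser=None)
    haps = collapse_haplotypes(aln)
    truth = {}
    with open(RESULTS / "sim_truth.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth[row["record_id"]] = row["truth"]

    cfg = ScreenConfig()
    verdicts = screen_dataset(haps, refs, cfg)

    with open(RESULTS / "verdicts.tsv", "w") as fh:
        fh.write("# k-of-6 rule (k_outside=%d): a haplotype is a putative numt when at\n"
                 "# least k profile metrics fall beyond their mtDNA expectation interval\n"
                 "# on the pseudogene side, or when it has an internal stop or indel\n"
                 % cfg.k_outside)
        fh.write("hap_id\tverdict\ttruth\tn_outside\tgc\tsuspicious_metrics\n")
        hap_by_id = {h.hap_id: h for h in haps}
        for v in verdicts:
            hap_truth = truth[hap_by_id[v.hap_id].members[0]]
            metrics = {r: list(rep.suspicious_metrics()) for r, rep in v.reports.items()}
            fh.write(f"{v.hap_id}\t{v.verdict}\t{hap_truth}\t{v.n_outside}\t"
                     f"{v.gc:.4f}\t{metrics}\n")
            print(f"{v.hap_id}: {v.verdict} (truth {hap_truth}; "
                  f"{v.n_outside} pseudogene-side deviations; GC {100 * v.gc:.1f}%)")
            for ref_id, rep in v.reports.items():
                obs = {m: f"{c.observed:.0f}" for m, c in rep.checks.items()}
                print(f"    vs {ref_id}: {obs} -> suspicious {rep.suspicious_metrics()}")

    suspects = [hap_by_id[v.hap_id] for v in verdicts if v.verdict == PUTATIVE_NUMT]
    if len(suspects) >= 2:
        print("cross-comparison of flagged haplotypes:")
        for (a, b), rep in cross_compare(suspects, cfg).items():
            if rep is None:
                print(f"  {a} vs {b}: identical, skipped")
            else:
                print(f"  {a} vs {b}: {rep.n_suspicious} pseudogene-side deviations "
                      f"({', '.join(rep.suspicious_metrics())})")
    print(f"wrote {RESULTS / 'verdicts.tsv'}")


if __name__ == "__main__":
    main()
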