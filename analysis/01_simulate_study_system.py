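#!/usr/bin/env python
"""Simulate the study system: a 42 kb / 63.4% GC / 47-gene phage genome, a
reference panel of diverged relatives organised into groups, and two labeled
synthetic viromes sampled from communities containing both.

Writes everything downstream steps need under results/synthetic_study/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cyanophage import recruitment as rec
from cyanophage import seq_core as sq
from cyanophage import synthetic_data as syn

# groups of genetic proximity mirroring a cultured-cyanopodovirus panel:
# two marine picocyanobacteria-phage clades, a freshwater clade, and a
# close relative group
PANEL_GROUPS = [
    ("MPP-A", 2, 0.60),
    ("MPP-B2", 2, 0.62),
    ("MPP-B3", 2, 0.60),
    ("Pf-WMP3-LIKE", 2, 0.55),
    ("SRP-LIKE", 2, 0.70),
]

VIROMES = {  # name -> (target weight, n_reads)
    "lake_virome": (0.30, 800),
    "ocean_virome": (0.08, 800),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic_study"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    spec = syn.GenomeSpec(length=42_000, gc=0.634, n_genes=47,
                          genome_id="S-SYN02", seed=args.seed)
    genome, genes = syn.generate_genome(spec)
    target = rec.TargetPhage(genome, genes)
    sq.write_fasta([genome], out / "target_genome.fasta")
    sq.write_gff3(genes, out / "target_genes.gff3")
    sq.write_fasta(target.proteome, out / "target_proteins.faa")
    summary = sq.genome_summary(genome, genes)
    print(f"target genome: {summary['length_bp']} bp, "
          f"GC {100 * summary['gc_fraction']:.1f}%, {summary['n_orfs']} genes")

    panel = syn.build_panel(target, PANEL_GROUPS, seed=args.seed + 1)
    manifest_rows = []
    for e in panel.entries:
        sq.write_fasta([e.genome], out / f"{e.phage_id}.fasta")
        sq.write_fasta(list(e.proteome), out / f"{e.phage_id}.faa")
        manifest_rows.append(
            {"phage_id": e.phage_id, "group": e.group_label,
             "genome_fasta": f"{e.phage_id}.fasta",
             "proteome_fasta": f"{e.phage_id}.faa"}
        )
    pd.DataFrame(manifest_rows).to_csv(out / "panel_manifest.tsv", sep="\t",
                                       index=False)
    print(f"panel: {len(panel)} members in {len(panel.groups)} groups")

    for vi, (name, (w_target, n_reads)) in enumerate(VIROMES.items()):
        w_member = (1.0 - w_target) / len(panel.entries)
        community = [(genome, w_target)] + [
            (e.genome, w_member) for e in panel.entries
        ]
        reads, truth = syn.simulate_metagenome(
            community, n_reads=n_reads, read_len=150, error_rate=0.01,
            seed=args.seed + 10 + vi, id_prefix=f"{name}_",
        )
        sq.write_fasta(reads, out / f"{name}.fasta")
        truth.to_csv(out / f"{name}_truth.tsv", sep="\t", index=False)
        n_target = (truth["genome_id"] == genome.id).sum()
        print(f"{name}: {n_reads} reads, {n_target} from the target genome")

    (out / "study_config.json").write_text(json.dumps(
        {"seed": args.seed, "genome": summary,
         "panel_groups": PANEL_GROUPS, "viromes": VIROMES}, indent=2,
        default=str) + "\n")


if __name__ == "__main__":
    main()
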