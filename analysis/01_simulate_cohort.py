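#!/usr/bin/env python
"""Simulate a synthetic two-patient cfDNA cohort.

SYN1 carries a detectable tumour fraction (tf = 0.30) and SYN2 sits in the
sub-percent regime (tf = 0.005) that deep-WGS plasma studies report for
early-stage disease. Both get matched germline/tumour/plasma pileups,
plasma fragment tables and truth sets under results/analysis/<patient>/.
"""

from pathlib import Path

from cfplasma.simulate import SimConfig, simulate_study, write_fasta, \
    write_fragments, write_gene_models, write_pileup, write_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

PATIENTS = {
    "SYN1": SimConfig(seed=101, plasma_tumour_fraction=0.30),
    "SYN2": SimConfig(seed=102, plasma_tumour_fraction=0.005),
}


def main():
    for patient, cfg in PATIENTS.items():
        out = OUT / patient
        out.mkdir(parents=True, exist_ok=True)
        study = simulate_study(cfg)
        write_fasta(study.reference, out / "reference.fa")
        write_gene_models(study.gene_models, out / "gene_models.tsv")
        for name, pileup in study.pileups.items():
            write_pileup(pileup, out / f"pileup_{name}.tsv")
        write_fragments(study.plasma_fragments, out / "fragments_plasma.tsv")
        write_fragments(study.germline_fragments, out / "fragments_germline.tsv")
        write_truth(study.truth, out / "truth.vcf", out / "truth.tsv",
                    cfg.chromosome_lengths())
        print(f"{patient}: tf={cfg.plasma_tumour_fraction}, "
              f"{len(study.truth.tumour)} tumour + "
              f"{len(study.truth.background)} background mutations, "
              f"{study.plasma_fragments['fragment_id'].nunique()} plasma fragments")


if __name__ == "__main__":
    main()
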