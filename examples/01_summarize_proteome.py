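"""Summarize one proteome: length statistics and disorder content.

Generates a small eukaryote-like synthetic proteome, runs primary-isoform
selection and X-exclusion, and prints the per-proteome summary row.
"""

import tempfile

import ldfingerprint as ld

with tempfile.TemporaryDirectory() as tmp:
    spec = ld.eukaryote_like("demo_euk", seed=1, n_proteins=500)
    paths = ld.generate_proteome(spec, tmp)

    prot = ld.read_proteome("demo_euk", paths["fasta"])
    prot = ld.load_scores(prot, paths["scores"])

    s = ld.summarize(prot)
    print(ld.summary_table([s]).to_string(index=False))
    print()
    print(
        f"{s.gene_number} proteins; median length {s.med_L:.0f} aa "
        f"(range {s.min_L}-{s.max_L}); {s.pct_idp:.1f}% are IDPs "
        f"(>= half of their residues disordered) and {s.pct_id_res:.1f}% of "
        "all residues are disordered on average."
    )
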