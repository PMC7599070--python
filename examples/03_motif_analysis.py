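"""Scan peptides for the S/T-x(2-3)-phi-L motif and contrast
positional amino-acid frequencies of candidates vs all sites."""

import holophos as hp

# two substrate peptides: one with the +4/+5 leucine doublet serving
# two adjacent phosphoacceptors, one with a single canonical site
for name, peptide in [("doublet peptide", "QQGKSSSTGNLLDKDDL"),
                      ("single-site peptide", "DPAQSASRENLLEEQ")]:
    print(name, peptide)
    for m in hp.scan_motif(peptide):
        print(f"  {m.target_residue}{m.target_position}: spacer "
              f"{m.spacer_len} ({m.match_class}), phi={m.phi_residue}")

# frequency contrast on a synthetic experiment
proteome, truth = hp.gen_proteome(seed=3)
table, _ = hp.gen_silac(truth, seed=3)
design = hp.SilacDesign(
    columns={s: s for s in ("r2H1L", "r3H1L", "r2L1H", "r3L1H")})
scored = hp.score_table(table, design).merge(
    table.df[["site_id", "window"]], on="site_id")
fore = hp.positional_frequency(
    scored.loc[scored["score"] > 2.5, "window"].tolist())
back = hp.positional_frequency(scored["window"].tolist())
contrast = hp.frequency_contrast(fore, back)
observed = contrast.where(fore.counts > 0)  # rank only observed residues
top = observed.stack().sort_values(ascending=False).head(6)
print("\nmost enriched observed (position, residue) in high scorers, log2:")
print(top.to_string())
# The planted consensus puts L at +4/+5 and acidic residues around it,
# so those cells should dominate the positive side of the contrast.
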