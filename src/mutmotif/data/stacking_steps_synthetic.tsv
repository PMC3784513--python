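# SYNTHETIC placeholder table of absolute base-stacking free energies
# dG(nu) for the 16 ordered dinucleotide steps, in arbitrary consistent
# energy units.  These are NOT published values: they honor only the
# qualitative ordering purine-purine >> purine-pyrimidine > pyrimidine-purine
# > pyrimidine-pyrimidine, with distinct per-step values to avoid ties.
# To reproduce published axes, supply a table of the epsilon=2 continuum-
# solvation stacking free energies via StackingStepTable.from_tsv().
step	dg
AA	7.5
AG	7.9
GA	7.7
GG	8.1
AC	5.6
AT	5.4
GC	5.9
GT	5.7
CA	4.4
CG	4.7
TA	4.2
TG	4.5
CC	3.5
CT	3.3
TC	3.4
TT	3.2
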