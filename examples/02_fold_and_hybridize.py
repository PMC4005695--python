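"""Fold a TIR and hybridize it with the anti-Shine-Dalgarno probe.

The folding engine returns the minimum-free-energy nested structure under
the package's simplified nearest-neighbor model; the duplex engine finds
the best intermolecular helix between the TIR and the 13-nt 3' tail of 16S
rRNA and decomposes its energy into duplex, exterior-loop (dangling ends)
and initiation terms.
"""

from seq2abundance import cofold_duplex, fold_mfe, structure_statistics
from seq2abundance.feature_catalog import DEFAULT_ANTI_SD
from seq2abundance.rna_energy import EnergyModel

tir = "TTCTCATTTAAGGAGGTAATTTATAATGGCAAAACGTATCGCTGAACTGCGTAAA"
model = EnergyModel.default()

structure = fold_mfe(tir, model)
unpaired, accessibility, dg = structure_statistics(structure, (21, 41))
print(f"TIR fold dG = {dg:.2f} kcal/mol")
print(f"dot-bracket: {structure.dot_bracket}")
print(f"accessibility around the start codon (-4..+16): {accessibility:.2f}")

hybrid = cofold_duplex(tir, DEFAULT_ANTI_SD, model)
print(f"16S:SD duplex: {hybrid.duplex_length} bp, "
      f"total dG = {hybrid.dg_total:.2f} kcal/mol")
print(f"  duplex {hybrid.dg_duplex:.2f} + exterior loop "
      f"{hybrid.dg_exterior:.2f} + init = total")
# A lower (more negative) total dG means tighter 16S binding; the exterior
# loop term is the dangling-end energy flanking the duplex — the feature
# whose weak binding associates with efficient initiation.
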