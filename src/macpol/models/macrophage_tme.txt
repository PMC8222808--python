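# Macrophage polarization in a tumor microenvironment - 29-node Boolean model.
#
# PROVENANCE: best-effort reconstruction of the published 29-node / 60-edge
# macrophage-polarization regulatory network (supplementary material SM1 of
# the source article; the original rule file was not retrievable in this
# build environment).  Rules encode the signaling cascades described in the
# article text and were calibrated against its reported qualitative results
# (phenotype spectrum, microenvironment and genetically-modified-macrophage
# behavior, cell-fate transitions).  See the repository README for details.
#
# Bit order of integer state encodings follows line order (first rule =
# bit 0).
targets, factors
# --- extracellular signals (sustained while present) ---
IFNG, IFNG
IFNB, IFNB
IL4, IL4
IL13, IL13
IL1B, IL1B
IGG, IGG
GCGCR, GCGCR
A2A, A2A
HYPOXIA, HYPOXIA
MCSF, MCSF
TGFB, TGFB
# --- receptors and kinases ---
TLR4, TLR4 | FRA1
FRA1, TLR4
JAK2, MCSF
STAT5, JAK2
ERK, IGG | (ERK & !NFKB)
# --- master transcription factors ---
NFKB, (TLR4 | STAT5) & !STAT6 & !KLF4 & !STAT3 & !A2A
STAT1, IFNG | IFNB | (STAT1 & !SOCS1)
SOCS1, STAT6 | NFKB
KLF4, STAT6
STAT6, (IL4 | IL13) & !STAT1 & !NFKB & !TNFA
STAT3, IL10 & (GCGCR | IL6) & !STAT1 & !NFKB
AP1, (IL1B | AP1) & !NFKB
HIF1A, (HYPOXIA | TGFB | A2A | STAT3 | HIF1A) & !NFKB
# --- secreted factors ---
IL6, NFKB
TNFA, NFKB | AP1
IL10, STAT6 | HIF1A
IL12, NFKB | STAT1
VEGF, HIF1A | STAT3
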