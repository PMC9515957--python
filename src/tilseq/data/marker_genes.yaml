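# Default marker-gene table for T-cell phenotype classification.
#
# One entry per phenotype; values are HGNC gene symbols (uppercase). The
# classifier scores each cell as the mean z-scaled log-normalized expression
# over a phenotype's markers and assigns the argmax phenotype when it clears
# the runner-up by a configurable margin. Users may supply their own table
# with the same structure; lists must be non-empty.
#
# The sets below are deliberately compact and (near-)disjoint so that each
# phenotype has an unambiguous transcriptional signature:
#   naive  - lymph-node homing / quiescence
#   T_scm  - stem-cell-like memory (early-memory costimulation)
#   T_cm   - central memory
#   T_em   - effector memory (cytotoxic-granule adjacent)
#   T_eff  - terminal effector / cytotoxic
#   Th1/Th2/Th17 - CD4 helper lineages (master TFs + chemokine receptors)
#   T_reg  - regulatory CD4
naive: [CCR7, SELL, TCF7, LEF1]
T_scm: [IL7R, CD27, CD28, FAS]
T_cm: [GPR183, CD44, IL2RB, AQP3]
T_em: [GZMK, CCL5, CST7, NKG7]
T_eff: [GZMB, PRF1, IFNG, KLRG1]
Th1: [TBX21, CXCR3, IL12RB2, STAT4]
Th2: [GATA3, CCR4, IL4R, STAT6]
Th17: [RORC, CCR6, IL23R, IL17RA]
T_reg: [FOXP3, IL2RA, IKZF2, ENTPD1]
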