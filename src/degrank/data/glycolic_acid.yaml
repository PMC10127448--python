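# Glycolic acid (GA) production pathway from oxaloacetate.
#
# Four heterologous pathway steps plus one auxiliary NADPH-supply enzyme:
#   OXA    oxaloacetase (Aspergillus niger), oxaloacetate hydrolysis
#   FAT2   oxalate-CoA ligase (S. cerevisiae FAT2)
#   PANE2  oxalyl-CoA reductase (Methylobacterium extorquens panE2)
#   GLYR1  glyoxylate reductase (Arabidopsis thaliana GLYR1)
#   GAPN   NADP-dependent non-phosphorylating glyceraldehyde-3-phosphate
#          dehydrogenase (Triticum aestivum) — boosts NADPH supply for
#          GLYR1; auxiliary, not a pathway member for distance purposes.
#
# Stoichiometries completed from standard biochemical references:
#   OXA:   oxaloacetate + H2O -> oxalate + acetate + H+
#   FAT2:  oxalate + CoA + ATP -> oxalyl-CoA + AMP + diphosphate
#   PANE2: oxalyl-CoA + NADPH + H+ -> glyoxylate + NADP+ + CoA
#   GLYR1: glyoxylate + NADPH + H+ -> glycolate + NADP+
#   GAPN:  glyceraldehyde 3-phosphate + NADP+ + H2O -> 3-phosphoglycerate
#          + NADPH + 2 H+
#
# Glyoxylate is mapped to the host's own cytosolic pool.
name: glycolic_acid
host_mapping:
  oaa_host: "oxaloacetate [cytoplasm]"
  h2o_host: "H2O [cytoplasm]"
  h_host: "H+ [cytoplasm]"
  acetate_host: "acetate [cytoplasm]"
  atp_host: "ATP [cytoplasm]"
  amp_host: "AMP [cytoplasm]"
  ppi_host: "diphosphate [cytoplasm]"
  coa_host: "coenzyme A [cytoplasm]"
  nadph_host: "NADPH [cytoplasm]"
  nadp_host: "NADP(+) [cytoplasm]"
  glx_host: "glyoxylate [cytoplasm]"
  g3p_host: "glyceraldehyde 3-phosphate [cytoplasm]"
  pg3_host: "3-phosphoglycerate [cytoplasm]"
new_metabolites:
  - {id: oxalate_ga_c, name: oxalate, compartment: cytoplasm, formula: C2O4}
  - {id: oxalylcoa_ga_c, name: oxalyl-CoA, compartment: cytoplasm}
  - {id: glycolate_ga_c, name: glycolate, compartment: cytoplasm, formula: C2H3O3}
reactions:
  - id: OXA
    name: oxaloacetase
    stoich: {oaa_host: -1, h2o_host: -1, oxalate_ga_c: 1, acetate_host: 1, h_host: 1}
    lb: 0
    ub: 1000
    gpr: AnOXA
  - id: FAT2
    name: oxalate-CoA ligase
    stoich: {oxalate_ga_c: -1, coa_host: -1, atp_host: -1, oxalylcoa_ga_c: 1, amp_host: 1, ppi_host: 1}
    lb: 0
    ub: 1000
    gpr: ScFAT2
  - id: PANE2
    name: oxalyl-CoA reductase
    stoich: {oxalylcoa_ga_c: -1, nadph_host: -1, h_host: -1, glx_host: 1, nadp_host: 1, coa_host: 1}
    lb: 0
    ub: 1000
    gpr: MePANE2
  - id: GLYR1
    name: glyoxylate reductase
    stoich: {glx_host: -1, nadph_host: -1, h_host: -1, glycolate_ga_c: 1, nadp_host: 1}
    lb: 0
    ub: 1000
    gpr: AtGLYR1
  - id: GAPN
    name: NADP-dependent glyceraldehyde-3-phosphate dehydrogenase
    stoich: {g3p_host: -1, nadp_host: -1, h2o_host: -1, pg3_host: 1, nadph_host: 1, h_host: 2}
    lb: 0
    ub: 1000
    gpr: TaGAPN
    auxiliary: true
  - id: EX_glycolate
    name: glycolate export
    stoich: {glycolate_ga_c: -1}
    lb: 0
    ub: 1000
product_exchange: EX_glycolate
product_metabolite: glycolate_ga_c
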