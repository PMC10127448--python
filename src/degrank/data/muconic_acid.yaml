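# cis,cis-muconic acid (MA) production pathway from 3-dehydroshikimate.
#
# Three heterologous pathway steps plus one auxiliary cofactor-supply enzyme:
#   AROZ  3-dehydroshikimate dehydratase (Podospora anserina AroZ)
#   AROY  protocatechuate decarboxylase (Klebsiella pneumoniae AroY)
#   HQD2  catechol 1,2-dioxygenase (Candida albicans Hqd2)
#   PAD1  FMN prenyltransferase (S. cerevisiae Pad1) — supplies the prenylated
#         FMN cofactor of AroY; auxiliary, not a pathway member for distance
#         purposes.
#
# Stoichiometries completed from standard biochemical references:
#   AROZ: dehydration, DHS -> protocatechuate + H2O
#   AROY: non-oxidative decarboxylation, PCA + H+ -> catechol + CO2
#   HQD2: intradiol ring cleavage, catechol + O2 -> cis,cis-muconate + 2 H+
#   PAD1: FMN + dimethylallyl-PP -> prenyl-FMN + diphosphate
#
# host_mapping values are resolved against the host model by exact metabolite
# id first, then by unique "name [compartment]" match, so the file ports
# across genome-scale model versions whose ids differ.
name: muconic_acid
host_mapping:
  dhs_host: "3-dehydroshikimate [cytoplasm]"
  h2o_host: "H2O [cytoplasm]"
  h_host: "H+ [cytoplasm]"
  co2_host: "carbon dioxide [cytoplasm]"
  o2_host: "oxygen [cytoplasm]"
  fmn_host: "FMN [cytoplasm]"
  dmapp_host: "dimethylallyl diphosphate [cytoplasm]"
  ppi_host: "diphosphate [cytoplasm]"
new_metabolites:
  - {id: pca_ma_c, name: protocatechuate, compartment: cytoplasm, formula: C7H5O4}
  - {id: catechol_ma_c, name: catechol, compartment: cytoplasm, formula: C6H6O2}
  - {id: ccmuconate_ma_c, name: cis,cis-muconate, compartment: cytoplasm, formula: C6H4O4}
  - {id: prfmn_ma_c, name: prenyl-FMN, compartment: cytoplasm}
reactions:
  - id: AROZ
    name: 3-dehydroshikimate dehydratase
    stoich: {dhs_host: -1, pca_ma_c: 1, h2o_host: 1}
    lb: 0
    ub: 1000
    gpr: PaAROZ
  - id: AROY
    name: protocatechuate decarboxylase
    stoich: {pca_ma_c: -1, h_host: -1, catechol_ma_c: 1, co2_host: 1}
    lb: 0
    ub: 1000
    gpr: KpAROY
  - id: HQD2
    name: catechol 1,2-dioxygenase
    stoich: {catechol_ma_c: -1, o2_host: -1, ccmuconate_ma_c: 1, h_host: 2}
    lb: 0
    ub: 1000
    gpr: CaHQD2
  - id: PAD1_PRFMN
    name: FMN prenyltransferase (AroY cofactor supply)
    stoich: {fmn_host: -1, dmapp_host: -1, prfmn_ma_c: 1, ppi_host: 1}
    lb: 0
    ub: 1000
    gpr: ScPAD1
    auxiliary: true
  - id: EX_ccmuconate
    name: cis,cis-muconate export
    stoich: {ccmuconate_ma_c: -1}
    lb: 0
    ub: 1000
product_exchange: EX_ccmuconate
product_metabolite: ccmuconate_ma_c
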