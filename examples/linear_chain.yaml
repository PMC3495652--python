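# Three-metabolite linear chain with end-product feedback inhibition:
# X1 -> X2 -> X3, with the input flux v1 inhibited by X3.
format: dfe-topology/1
metabolites:
  - {name: X1, measured: true}
  - {name: X2, measured: true}
  - {name: X3, measured: true}
fluxes:
  - {name: v1, depends_on: [X3]}
  - {name: v2, depends_on: [X1]}
  - {name: v3, depends_on: [X2]}
  - {name: v4, depends_on: [X3]}
equations:
  X1: [{flux: v1, coeff: 1}, {flux: v2, coeff: -1}]
  X2: [{flux: v2, coeff: 1}, {flux: v3, coeff: -1}]
  X3: [{flux: v3, coeff: 1}, {flux: v4, coeff: -1}]
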