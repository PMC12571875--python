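# Per-condition, per-compartment median cell-type compositions (percent).
# Glomerular medians for podocyte, PEC, mesangial, fibrotic mesangial and
# macrophage, periglomerular and tubulointerstitial T-cell medians follow the
# published cohort values for crescentic glomerulonephritis; the remaining
# fractions (endothelium, tubular types, stromal and minor immune populations)
# are plausible fill-ins chosen so each compartment sums to 100.
# The ANCA-GN glomerular PEC median (12) interpolates the published monotone
# control < SLE < anti-GBM trend.
control:
  glomerular:
    podocyte: 30.0
    PEC: 6.0
    mesangial: 17.9
    fibrotic_mesangial: 1.6
    macrophage: 0.4
    endothelial: 34.0
    T_cell: 0.6
    B_cell: 0.2
    plasma_cell: 0.1
    fibroblast: 1.2
    proximal_tubule: 5.0
    TAL: 2.0
    collecting_duct: 1.0
  periglomerular:
    proximal_tubule: 38.0
    TAL: 18.0
    collecting_duct: 8.0
    endothelial: 14.0
    fibroblast: 12.0
    macrophage: 3.0
    T_cell: 1.1
    B_cell: 0.5
    plasma_cell: 0.4
    mesangial: 2.0
    PEC: 3.0
  tubulointerstitial:
    proximal_tubule: 45.0
    TAL: 20.0
    collecting_duct: 10.0
    endothelial: 12.0
    fibroblast: 8.0
    macrophage: 2.5
    T_cell: 1.13
    B_cell: 0.5
    plasma_cell: 0.37
    mesangial: 0.5
SLE:
  glomerular:
    podocyte: 25.9
    PEC: 8.0
    mesangial: 10.2
    fibrotic_mesangial: 2.0
    macrophage: 2.0
    endothelial: 31.0
    T_cell: 1.2
    B_cell: 0.4
    plasma_cell: 0.3
    fibroblast: 2.0
    proximal_tubule: 10.0
    TAL: 4.0
    collecting_duct: 3.0
  periglomerular:
    proximal_tubule: 35.0
    TAL: 16.0
    collecting_duct: 7.0
    endothelial: 13.5
    fibroblast: 13.0
    macrophage: 5.0
    T_cell: 2.5
    B_cell: 1.2
    plasma_cell: 0.8
    mesangial: 2.0
    PEC: 4.0
  tubulointerstitial:
    proximal_tubule: 41.0
    TAL: 19.0
    collecting_duct: 9.0
    endothelial: 12.0
    fibroblast: 10.0
    macrophage: 4.0
    T_cell: 2.28
    B_cell: 1.2
    plasma_cell: 0.8
    mesangial: 0.72
ANCA-GN:
  glomerular:
    podocyte: 25.0
    PEC: 12.0
    mesangial: 7.1
    fibrotic_mesangial: 6.4
    macrophage: 2.0
    endothelial: 27.0
    T_cell: 1.8
    B_cell: 0.6
    plasma_cell: 0.4
    fibroblast: 2.7
    proximal_tubule: 9.0
    TAL: 4.0
    collecting_duct: 2.0
  periglomerular:
    proximal_tubule: 31.0
    TAL: 14.0
    collecting_duct: 6.5
    endothelial: 12.5
    fibroblast: 15.0
    macrophage: 6.5
    T_cell: 4.8
    B_cell: 1.8
    plasma_cell: 1.4
    mesangial: 2.5
    PEC: 4.0
  tubulointerstitial:
    proximal_tubule: 37.0
    TAL: 17.0
    collecting_duct: 8.0
    endothelial: 12.0
    fibroblast: 12.5
    macrophage: 5.5
    T_cell: 3.82
    B_cell: 1.6
    plasma_cell: 1.1
    mesangial: 1.48
anti-GBM:
  glomerular:
    podocyte: 23.8
    PEC: 15.0
    mesangial: 4.3
    fibrotic_mesangial: 8.8
    macrophage: 7.8
    endothelial: 24.0
    T_cell: 2.0
    B_cell: 0.8
    plasma_cell: 0.5
    fibroblast: 3.0
    proximal_tubule: 6.0
    TAL: 2.5
    collecting_duct: 1.5
  periglomerular:
    proximal_tubule: 28.0
    TAL: 13.0
    collecting_duct: 6.0
    endothelial: 12.0
    fibroblast: 16.0
    macrophage: 8.0
    T_cell: 7.4
    B_cell: 2.5
    plasma_cell: 2.1
    mesangial: 2.0
    PEC: 3.0
  tubulointerstitial:
    proximal_tubule: 35.0
    TAL: 16.0
    collecting_duct: 7.5
    endothelial: 12.0
    fibroblast: 13.5
    macrophage: 6.5
    T_cell: 4.4
    B_cell: 2.0
    plasma_cell: 1.4
    mesangial: 1.7
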