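# Default shell geometry per barcode class (nm).
# Qt (T=4) and Tm (T=1) outer diameters follow the reported ~40 nm and
# ~25 nm; Mx (T=3) is an intermediate 32 nm (only the ordering
# Qt > Mx > Tm is reported).  Shell thickness and the per-metallothionein
# ring width are rendering defaults chosen so that the three-layer Qt
# lumen vanishes (20 - 3.5 - 3*5.5 = 0: no bright center).
QT_1M: {outer_diameter_nm: 40.0, shell_thickness_nm: 3.5, metal_layers: 1,
        ring_width_per_layer_nm: 5.5, triangulation_number: 4}
QT_2M: {outer_diameter_nm: 40.0, shell_thickness_nm: 3.5, metal_layers: 2,
        ring_width_per_layer_nm: 5.5, triangulation_number: 4}
QT_3M: {outer_diameter_nm: 40.0, shell_thickness_nm: 3.5, metal_layers: 3,
        ring_width_per_layer_nm: 5.5, triangulation_number: 4}
MX_1M: {outer_diameter_nm: 32.0, shell_thickness_nm: 3.5, metal_layers: 1,
        ring_width_per_layer_nm: 5.5, triangulation_number: 3}
MX_2M: {outer_diameter_nm: 32.0, shell_thickness_nm: 3.5, metal_layers: 2,
        ring_width_per_layer_nm: 5.5, triangulation_number: 3}
TM_1M: {outer_diameter_nm: 25.0, shell_thickness_nm: 3.5, metal_layers: 1,
        ring_width_per_layer_nm: 5.5, triangulation_number: 1}
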