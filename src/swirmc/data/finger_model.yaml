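# Default finger-tissue model: an eight-interface semi-infinite slab stack.
# thickness_mm: null lets the hypodermis fill the volume down to total_depth_mm.
g: 0.9
n_tissue: 1.4
n_external: 1.0
total_depth_mm: 13.0
lateral_mm: 13.0
v_lipid_blood: 0.01
c_ref_mmol_l: 100.0
scatter_convention: reduced
layers:
  - {name: stratum_corneum,        thickness_mm: 0.02, v_blood: 0.00, v_water: 0.05, v_melanin: 0.00, scatter_class: skin}
  - {name: epidermis,              thickness_mm: 0.25, v_blood: 0.00, v_water: 0.20, v_melanin: 0.02, scatter_class: skin}
  - {name: papillary_dermis,       thickness_mm: 0.10, v_blood: 0.04, v_water: 0.50, v_melanin: 0.00, scatter_class: skin}
  - {name: upper_blood_net_dermis, thickness_mm: 0.08, v_blood: 0.30, v_water: 0.60, v_melanin: 0.00, scatter_class: skin}
  - {name: reticular_dermis,       thickness_mm: 0.20, v_blood: 0.04, v_water: 0.70, v_melanin: 0.00, scatter_class: skin}
  - {name: deep_blood_net_dermis,  thickness_mm: 0.30, v_blood: 0.10, v_water: 0.70, v_melanin: 0.00, scatter_class: skin}
  - {name: hypodermis,             thickness_mm: null, v_blood: 0.05, v_water: 0.70, v_melanin: 0.00, scatter_class: fat}
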