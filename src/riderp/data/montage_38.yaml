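# Default 38-site 10-20 scalp layout with mastoid reference pair.
# positions: idealized 2-D head-surface projection (x = right, y = anterior),
# used for topography export and for synthetic scalp weighting.
name: standard-38
channels: [FP1, FPz, FP2, AF7, AF3, AF4, AF8, F7, F3, Fz, F4, F8,
           FT7, FC3, FCz, FC4, FT8, T7, C3, Cz, C4, T8,
           TP7, CP3, CPz, CP4, TP8, P7, P3, Pz, P4, P8,
           PO7, PO5, POz, PO6, PO8, Oz]
mastoids: [M1, M2]
midline: [FPz, Fz, FCz, Cz, CPz, Pz, POz, Oz]
rois:
  left_anterior: [F7, F3, FT7, FC3]
  right_anterior: [F4, F8, FC4, FT8]
  left_central: [T7, C3, TP7, CP3]
  right_central: [C4, T8, CP4, TP8]
  left_posterior: [P7, P3, PO7, PO5]
  right_posterior: [P4, P8, PO6, PO8]
regions:
  anterior: [left_anterior, right_anterior]
  central: [left_central, right_central]
  posterior: [left_posterior, right_posterior]
positions:
  FP1: [-0.2944, 0.8392]
  FPz: [0.0011, 0.8825]
  FP2: [0.2987, 0.8490]
  AF7: [-0.5484, 0.6857]
  AF3: [-0.3370, 0.7684]
  AF4: [0.3571, 0.7773]
  AF8: [0.5574, 0.6966]
  F7: [-0.7026, 0.4247]
  F3: [-0.5024, 0.5311]
  Fz: [0.0031, 0.5851]
  F4: [0.5184, 0.5430]
  F8: [0.7304, 0.4442]
  FT7: [-0.8077, 0.1412]
  FC3: [-0.6018, 0.2272]
  FCz: [0.0038, 0.2739]
  FC4: [0.6229, 0.2372]
  FT8: [0.8182, 0.1542]
  T7: [-0.8416, -0.1602]
  C3: [-0.6536, -0.1163]
  Cz: [0.0040, -0.0917]
  C4: [0.6712, -0.1090]
  T8: [0.8508, -0.1502]
  TP7: [-0.8483, -0.4602]
  CP3: [-0.6356, -0.4701]
  CPz: [0.0039, -0.4732]
  CP4: [0.6661, -0.4664]
  TP8: [0.8555, -0.4555]
  P7: [-0.7243, -0.7345]
  P3: [-0.5301, -0.7879]
  Pz: [0.0032, -0.8111]
  P4: [0.5567, -0.7856]
  P8: [0.7306, -0.7307]
  PO7: [-0.5484, -0.9753]
  PO5: [-0.4842, -0.9934]
  POz: [0.0022, -1.0218]
  PO6: [0.4982, -0.9945]
  PO8: [0.5567, -0.9763]
  Oz: [0.0011, -1.1489]
  M1: [-0.8608, -0.4499]
  M2: [0.8579, -0.4501]
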