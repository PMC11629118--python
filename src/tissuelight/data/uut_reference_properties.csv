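tissue,wavelength_nm,mu_a,mu_a_sd,mu_sp,mu_sp_sd
human_ureter,410,2.16,0.84,3.47,1.33
human_ureter,445,1.26,0.56,3.29,0.98
human_ureter,450,0.90,0.45,3.26,0.91
human_ureter,510,0.53,0.32,2.58,0.63
human_ureter,532,0.65,0.44,2.38,0.58
human_ureter,545,0.77,0.51,2.28,0.56
human_ureter,580,0.62,0.43,2.02,0.47
human_ureter,630,0.25,0.09,1.74,0.36
human_ureter,635,0.25,0.09,1.71,0.35
human_ureter,664,0.23,0.08,1.56,0.31
human_ureter,690,0.21,0.07,1.42,0.27
human_fat,410,2.53,0.83,1.22,0.30
human_fat,445,1.66,0.62,1.64,0.43
human_fat,450,1.51,0.58,1.66,0.43
human_fat,510,0.73,0.34,1.56,0.33
human_fat,532,1.00,0.59,1.49,0.34
human_fat,545,1.05,0.64,1.46,0.32
human_fat,580,0.93,0.57,1.41,0.27
human_fat,630,0.20,0.05,1.55,0.24
human_fat,635,0.20,0.04,1.55,0.23
human_fat,664,0.18,0.03,1.53,0.22
human_fat,690,0.17,0.03,1.48,0.20
ureteral_carcinoma,410,1.23,0.20,2.10,0.32
ureteral_carcinoma,445,0.85,0.13,2.06,0.37
ureteral_carcinoma,450,0.68,0.09,2.09,0.40
ureteral_carcinoma,510,0.38,0.05,1.78,0.30
ureteral_carcinoma,532,0.40,0.09,1.69,0.31
ureteral_carcinoma,545,0.45,0.12,1.63,0.31
ureteral_carcinoma,580,0.36,0.10,1.50,0.28
ureteral_carcinoma,630,0.20,0.04,1.37,0.23
ureteral_carcinoma,635,0.19,0.04,1.35,0.23
ureteral_carcinoma,664,0.19,0.03,1.26,0.22
ureteral_carcinoma,690,0.17,0.03,1.16,0.20
renal_pelvic_carcinoma,410,1.33,0.37,2.80,0.74
renal_pelvic_carcinoma,445,0.89,0.27,2.85,0.65
renal_pelvic_carcinoma,450,0.69,0.18,2.88,0.58
renal_pelvic_carcinoma,510,0.38,0.10,2.53,0.46
renal_pelvic_carcinoma,532,0.42,0.13,2.36,0.46
renal_pelvic_carcinoma,545,0.48,0.17,2.26,0.47
renal_pelvic_carcinoma,580,0.38,0.13,2.12,0.41
renal_pelvic_carcinoma,630,0.17,0.03,2.07,0.34
renal_pelvic_carcinoma,635,0.16,0.02,2.06,0.34
renal_pelvic_carcinoma,664,0.15,0.02,1.95,0.33
renal_pelvic_carcinoma,690,0.14,0.02,1.83,0.32
porcine_ureter,410,1.19,0.57,4.88,1.16
porcine_ureter,445,0.68,0.27,4.24,0.96
porcine_ureter,450,0.50,0.16,4.23,0.92
porcine_ureter,510,0.36,0.09,3.34,0.70
porcine_ureter,532,0.40,0.11,3.02,0.64
porcine_ureter,545,0.44,0.14,2.86,0.62
porcine_ureter,580,0.39,0.11,2.54,0.54
porcine_ureter,630,0.29,0.05,2.20,0.46
porcine_ureter,635,0.29,0.05,2.17,0.46
porcine_ureter,664,0.28,0.05,1.99,0.42
porcine_ureter,690,0.27,0.05,1.84,0.39
porcine_fat,410,0.72,0.26,3.65,0.64
porcine_fat,445,0.24,0.06,3.87,0.38
porcine_fat,450,0.21,0.05,3.87,0.36
porcine_fat,510,0.15,0.02,3.66,0.32
porcine_fat,532,0.18,0.04,3.47,0.34
porcine_fat,545,0.19,0.05,3.39,0.33
porcine_fat,580,0.18,0.05,3.26,0.32
porcine_fat,630,0.12,0.02,3.24,0.30
porcine_fat,635,0.12,0.02,3.22,0.30
porcine_fat,664,0.11,0.02,3.13,0.30
porcine_fat,690,0.11,0.02,3.04,0.29
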