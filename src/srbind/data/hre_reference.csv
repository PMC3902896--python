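# Reference GR-HRE panel: apparent (K_app) and total (K_tot) binding
# affinities with ligand-induced fold-activation at the 100 ng
# expression-vector dose. Units: K_app in nM; K_tot in fM2, read as
# 1e-15 M^2 (femto-[M^2], NOT (1e-15 M)^2 -- see binding_core docs).
# k_*_sd are +/- SD; fa_sem is +/- SEM (n = 3).
name,sequence,k_app_nm,k_app_sd_nm,k_tot_fm2,k_tot_sd_fm2,fold_activation,fa_sem
Pal,AGAACAaaaTGTTCT,32,7,0.800,0.134,2.4,0.19
CGT,AGAACAtttTGTACG,34,5,0.877,0.123,2.3,0.23
SGK,AGAACAtttTGTCCG,110,31,7.09,1.75,1.7,0.12
Cons,AGAACAaaaTGTACC,125,29,8.55,1.42,2.6,0.08
FKBP5,AGAACAgggTGTTCT,356,73,64.9,7.80,1.6,0.12
GILZ,AGAACAttgGGTTCC,490,125,105,16.4,1.2,0.14
TAT4,AGAACAtcccTGTACA,2000,809,558,10.4,1.2,0.07
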