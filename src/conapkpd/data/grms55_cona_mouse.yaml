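# Reported parameter estimates of the GRMS-55 PK/PD/disease-progression model
# in ConA-induced hepatitis (female BALB/c mice; IP doses 50 and 100 mg/kg,
# IV ConA 20 mg/kg at 0.5 h after dosing).
#
# Baselines (R0_*) were not published; the values below are the package's
# documented assumption for synthetic-data generation (healthy-mouse serum
# levels of plausible magnitude). Units: drug mg/L, cytokines ng/L,
# transaminases U/L, time h, dose mg/kg.

# pharmacokinetic
Vd_F: 1.81      # L/kg, apparent volume of distribution
ka: 1.49        # 1/h, absorption rate constant
ke: 4.59        # 1/h, elimination rate constant (flip-flop: ka < ke)

# pharmacodynamic
tau: 0.405      # h, mean transit time (shared by all chains)
kout_IFNg: 0.234
kout_IL6: 0.531
kout_TNFa: 0.209
kout_IL10: 1.841
IC50_IFNg: 12.27   # mg/L
IC50_IL6: 13.40    # mg/L
IC50_TNFa: 7.97    # mg/L
S_IFNg: 5856
S_TNFa: 453.9
S_IL6: 10320
S_IL10: 2.035
kin_IL10_dis: 160.8   # ng/L/h
I_IL10_IFNg: 0.0002   # L/ng
Imax_TNFa: 1.0        # fixed
Imax_IFNg: 1.0        # fixed
Imax_IL6: 1.0         # fixed

# disease progression
S_ALT_TNFa: 0.0072
S_ALT_IFNg: 0.0002
kout_ALT: 0.0997
S_AST_TNFa: 0.7727
S_AST_IFNg: 0.0007
kout_AST: 0.0817
alpha: 1.5            # fixed
beta: 1.5             # fixed

# baselines (package assumption; supply measured values for real data)
R0_TNFa: 10.0
R0_IFNg: 5.0
R0_IL6: 5.0
R0_IL10: 20.0
R0_ALT: 35.0
R0_AST: 60.0

cona_time: 0.5        # h after drug dose
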