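# Default physiological constants for the pituitary-thyroid feedback model.
#
# The source publications of the SPINA model family report these estimated
# constants for distribution, elimination and plasma protein binding of the
# thyroid hormones; they are not patient-specific and are fully overridable
# (pass a file like this one, or a ModelConstants instance, to any operation).
#
# Units are stated per key; concentrations of the binding proteins are molar.

d_t      = 2.75      # EC50 of TSH at its thyroid receptor, mIU/L
alpha_t  = 0.1       # dilution factor for T4 (reciprocal volume of distribution), 1/L
beta_t   = 1.1e-6    # clearance exponent for T4, 1/s
k41      = 2.0e10    # association constant T4-TBG, L/mol
k42      = 2.0e8     # association constant T4-TTR, L/mol
tbg      = 3.0e-7    # thyroxine-binding globulin concentration, mol/L
ttr      = 4.5e-6    # transthyretin concentration, mol/L
alpha_31 = 0.026     # dilution factor for T3, 1/L
beta_31  = 8.0e-6    # clearance exponent for T3, 1/s
k_m1     = 500.0     # Michaelis constant of type-1 deiodinase, nmol/L
k30      = 2.0e9     # association constant T3-TBG, L/mol
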