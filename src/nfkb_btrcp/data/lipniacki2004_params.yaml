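# Rate constants of the canonical NF-kB pathway model (Lipniacki et al. 2004,
# J Theor Biol 228:195-215), the base model of the beta-TrCP extension.
# Units: concentrations in uM, time in seconds.
kprod: 2.5e-5   # constitutive IKKn synthesis (uM/s)
kdeg: 1.25e-4   # degradation of IKKn/IKKa/IKKi (1/s)
k1: 2.5e-3      # TNF-dependent IKKn activation (1/s)
k2: 0.1         # TNF- and A20-dependent IKKa inactivation (1/(uM s))
k3: 1.5e-3      # spontaneous IKKa inactivation (1/s)
a1: 0.5         # IkBa-NFkB association, cytoplasm and nucleus (1/(uM s))
a2: 0.2         # IKKa-IkBa association (1/(uM s))
a3: 1.0         # IKKa-(IkBa|NFkB) association (1/(uM s))
t1: 0.1         # IkBa degradation in IKKa|IkBa; scaled by beta-TrCP (1/s)
t2: 0.1         # IkBa degradation in IKKa|IkBa|NFkB; scaled by beta-TrCP (1/s)
c1: 5.0e-7      # NFkB-induced A20 transcription (1/s)
c2: 0.0         # constitutive A20 transcription (uM/s)
c3: 4.0e-4      # A20 mRNA degradation (1/s)
c4: 0.5         # A20 translation (1/s)
c5: 3.0e-4      # A20 protein degradation (1/s)
c1a: 5.0e-7     # NFkB-induced IkBa transcription (1/s)
c2a: 0.0        # constitutive IkBa transcription (uM/s)
c3a: 4.0e-4     # IkBa mRNA degradation (1/s)
c4a: 0.5        # IkBa translation (1/s)
c5a: 1.0e-4     # free IkBa degradation (1/s)
c6a: 2.0e-5     # IkBa degradation inside IkBa|NFkB (1/s)
c1c: 5.0e-7     # NFkB-induced cgen transcription (1/s)
c2c: 0.0        # constitutive cgen transcription (uM/s)
c3c: 4.0e-4     # cgen mRNA degradation (1/s)
i1: 2.5e-3      # NFkB nuclear import (1/s)
e2a: 1.0e-2     # IkBan|NFkBn nuclear export (1/s)
i1a: 1.0e-3     # IkBa nuclear import (1/s)
e1a: 5.0e-4     # IkBa nuclear export (1/s)
kv: 5.0         # cytoplasmic-to-nuclear volume ratio (dimensionless)
nf_total: 0.06  # conserved total NF-kB (uM, whole-cell basis)
btrcp_ref: 1.0e-3  # beta-TrCP reference concentration (uM) = 1 nM
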