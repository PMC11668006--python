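# Rule trigger lexicon: one trigger per line under its family section.
# Triggers match whole alphanumeric tokens, case-insensitively.  An entry
# ending in "." consumes that period (so "dr." can capture past it); label
# entries must end in ":".

[salutations]
dr.
dr
doctor
mr.
mr
mrs.
mrs
ms.
ms
miss
mx
prof.
prof
professor
sister
nurse
sir
madam

[labels]
name:
patient:
reporter:
consultant:
gp:
surname:
forename:
physician:
pharmacist:

[titles]
m.d.
md
ph.d.
phd
rn
frcp
mbbs
b.sc.
pharmd
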