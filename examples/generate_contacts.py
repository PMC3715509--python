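"""Generate a synthetic temporal contact network and summarize it.

Builds a small heavy-tailed contact sequence (configuration-model topology,
per-edge activity intervals covering 40% of the sampling time, bursty
interevent gaps) and prints the bookkeeping quantities: vertices N, contacted
pairs M, contacts L (= 10 M by construction), sampling time T and the
burstiness B of the pooled interevent times (0 = Poissonian, 1 = extremely
bursty).
"""

from temponet import SyntheticConfig, burstiness, generate_detailed, write_contacts

config = SyntheticConfig(N=200, mu=0.4, T=20_000, rng_seed=1)
real = generate_detailed(config)
cs = real.contacts

write_contacts(cs, "synthetic.contacts")
print(f"vertices N       = {cs.N}")
print(f"edges    M       = {cs.M}")
print(f"contacts L       = {cs.L}  (contacts per edge = {cs.L / cs.M:.1f})")
print(f"sampling time T  = {cs.T}")
print(f"burstiness B     = {burstiness(cs):.3f}")
print(f"leftover stubs   = {real.leftover_stubs}")
print("wrote synthetic.contacts (three-column 'i j t' format)")
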