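raw,canonical
annelids,mobile infauna
bottom fauna biodiversity,benthic biodiversity
polychaetes,mobile infauna
release of toxic substances,contaminant release
smothering by settling sediment,sediment deposition
turbidity near the seabed,suspended sediment near seafloor
worms,mobile infauna
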