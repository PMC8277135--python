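node,category
depth of extracted sediment,operational factor
duration of extraction,operational factor
mining intensity,operational factor
mining tool operation,operational factor
processing return technique,operational factor
vessel operations,operational factor
volume of extraction,operational factor
contaminant release,pressure
loss of hard substrate,pressure
modification of seafloor substrate,pressure
modification of seafloor topography,pressure
nodule removal,pressure
release of nutrients,pressure
sediment deposition,pressure
suspended sediment in water column,pressure
suspended sediment near seafloor,pressure
underwater noise,pressure
contaminants in sediment,environmental condition
near-bottom currents,environmental condition
nutrient concentration in sediment,environmental condition
organic content of sediment,environmental condition
oxygen conditions,environmental condition
pore water composition,environmental condition
salinity,environmental condition
sediment grain size,environmental condition
sediment type,environmental condition
stratification,environmental condition
temperature,environmental condition
water depth,environmental condition
benthic biodiversity,biological component
benthic primary production,biological component
demersal fish,biological component
demersal fish distribution,biological component
deposit feeders,biological component
ecosystem functioning,biological component
filter feeders,biological component
fish early life stages,biological component
food web structure,biological component
habitat availability,biological component
macrophytes,biological component
marine mammals,biological component
meiofauna,biological component
microbial communities,biological component
mobile epifauna,biological component
mobile infauna,biological component
pelagic fish,biological component
phytoplankton,biological component
recovery potential,biological component
reproductive success,biological component
seabirds,biological component
sessile epifauna,biological component
sessile infauna,biological component
zooplankton,biological component
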