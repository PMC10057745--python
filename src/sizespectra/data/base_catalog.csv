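name,realm,role,size_min,size_median,size_max,biomass,fold_uncertainty
Forest plants,terrestrial,producer,10.8,1.13e6,2.24e9,337.5,1.2
Grassland plants,terrestrial,producer,3.75e-3,4.32e6,1.34e9,112.5,1.2
Cryptogamic phototrophs,terrestrial,producer,1.15e-11,2.72e-10,87.5,2.5,2
Soil bacteria,terrestrial,consumer,7.37e-16,2.86e-14,1.15e-11,7.352,6
Soil archaea,terrestrial,consumer,7.37e-16,2.91e-14,4.72e-14,0.516,4
Soil protists,terrestrial,consumer,7.37e-13,7.37e-13,5.03e-11,1.605,4
Soil fungi,terrestrial,consumer,7.37e-13,1.53e-11,9.70e6,11.802,3
Terrestrial arthropods,terrestrial,consumer,1.50e-5,2.00e-4,6.00e2,0.212,15
Humans,terrestrial,consumer,3.75e3,8.13e3,1.13e4,0.055,1.1
Livestock,terrestrial,consumer,2.70e2,2.08e4,2.25e5,0.107,1.1
Wild land mammals,terrestrial,consumer,3.8e-2,2.53e3,1.65e6,0.003,4
Terrestrial nematodes,terrestrial,consumer,6.02e-13,5.00e-8,7.74e-8,0.002,10
Wild birds,terrestrial,consumer,0.27,6.67,1.50e4,0.199,10
Annelids,terrestrial,consumer,4.16e-8,2.59e-4,2.25e2,0.006,10
Reptiles,terrestrial,consumer,2.7e-2,1.05e2,1.80e5,0.003,100
Amphibians,terrestrial,consumer,3e-3,1.00,7.50e3,0.001,100
Mangroves,marine,producer,4.06e4,6.49e5,2.88e7,3.5,1.4
Seagrass,marine,producer,2.63e-3,7.53e4,6.91e7,0.11,10
Macroalgae,marine,producer,0.135,2.00,2.70e3,0.14,10
Bacterial picophytoplankton,marine,producer,5.00e-14,9.13e-14,1.67e-13,0.13,10
Green algae picophytoplankton,marine,producer,1.05e-13,1.49e-13,2.10e-13,0.30,10
Diatoms,marine,producer,2.4e-11,9.08e-9,5.11e-6,0.31,10
Phaeocystis,marine,producer,1.15e-11,5.24e-4,4.7e-2,0.28,10
Marine bacteria,marine,consumer,5.50e-16,1.32e-14,1.10e-4,1.327,1.8
Marine archaea,marine,consumer,1.47e-17,1.22e-14,9.90e-11,0.332,3
Marine protists,marine,consumer,1.44e-12,2.26e-12,7.37e-4,1.058,10
Marine arthropods,marine,consumer,3.537e-8,7.08e-6,3.00e3,0.940,10
Fish,marine,consumer,1.50e-4,0.627,4.63e6,0.668,8
Molluscs,marine,consumer,4.02e-4,1.0e-2,3.98e4,0.182,10
Cnidaria,marine,consumer,1.00e-5,5.09e-3,1.00e5,0.040,10
Hard corals,marine,consumer,6.41,1.54e3,1.68e7,0.653,4
Wild marine mammals,marine,consumer,4.05e3,7.42e4,2.99e7,0.004,1.4
Marine nematodes,marine,consumer,7.50e-9,1.80e-7,1.20e-5,0.014,10
Marine fungi,marine,consumer,5.89e-12,1.39e-11,1.89e-5,0.325,10
Subterranean bacteria,subterranean,consumer,9.81e-16,2.1e-14,5.90e-12,18.9,3
Subterranean archaea,subterranean,consumer,2.49e-15,2.1e-14,9.22e-14,8.1,3
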