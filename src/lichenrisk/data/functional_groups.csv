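genus,functional_group
Anomolobaria,cyano_large
Dendriscosticta,cyano_large
Lobaria,cyano_large
Nephroma,cyano_large
Peltigera,cyano_large
Pseudocyphellaria,cyano_large
Sticta,cyano_large
Collema,cyano_small_med
Dendriscocaulon,cyano_small_med
Enchylium,cyano_small_med
Erioderma,cyano_small_med
Fuscopannaria,cyano_small_med
Lathagrium,cyano_small_med
Leioderma,cyano_small_med
Leptogium,cyano_small_med
Leptochidium,cyano_small_med
Pannaria,cyano_small_med
Scytinium,cyano_small_med
Vahliella,cyano_small_med
Alectoria,forage_pendant
Bryocaulon,forage_pendant
Bryoria,forage_pendant
Nodobryoria,forage_pendant
Bunodophorun,forage_shrubby
Evernia,forage_shrubby
Letharia,forage_shrubby
Pseudevernia,forage_shrubby
Sphaerophorus,forage_shrubby
Teleoschistes,forage_shrubby
Ahtiana,matrix_med_large
Canoparmelia,matrix_med_large
Cetrelia,matrix_med_large
Crespoa,matrix_med_large
Esslingeriana,matrix_med_large
Flavoparmelia,matrix_med_large
Flavopunctelia,matrix_med_large
Heterodermia,matrix_med_large
Hypogymnia,matrix_med_large
Hypotrachyna,matrix_med_large
Imshaugia,matrix_med_large
Melanelixia,matrix_med_large
Melanohalea,matrix_med_large
Menegazzia,matrix_med_large
Montanelia,matrix_med_large
Myelochroa,matrix_med_large
Niebla,matrix_med_large
Parmelia,matrix_med_large
Parmelina,matrix_med_large
Parmotrema,matrix_med_large
Physcia,matrix_med_large
Physconia,matrix_med_large
Platismatia,matrix_med_large
Punctelia,matrix_med_large
Teloschistes,matrix_med_large
Tuckermanella,matrix_med_large
Tuckermannopsis,matrix_med_large
Usnocetraria,matrix_med_large
Vulpicida,matrix_med_large
Anaptychia,matrix_small
Bulbothrix,matrix_small
Candelaria,matrix_small
Cavernularia,matrix_small
Cladonia,matrix_small
Coccocarpia,matrix_small
Hyperphyscia,matrix_small
Kaernefeltia,matrix_small
Loxosporopsis,matrix_small
Parmeliella,matrix_small
Parmeliopsis,matrix_small
Phaeophyscia,matrix_small
Physciella,matrix_small
Placidium,matrix_small
Polycaulon,matrix_small
Polychidium,matrix_small
Pyxine,matrix_small
Rusavskia,matrix_small
Xanthomendoza,matrix_small
Xanthoria,matrix_small
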