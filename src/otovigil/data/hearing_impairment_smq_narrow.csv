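term,code
Acoustic stimulation tests abnormal,10000526
Altered pitch perception,10075083
Audiogram abnormal,10003761
Auditory disorder,10003778
Auditory recruitment,10003789
Autophony,10048827
Barotitis media,10004129
Bone anchored hearing aid implantation,10070723
Cochlea implant,10009830
Conductive deafness,10010280
Deafness bilateral,10052556
Deafness neurosensory,10011891
Deafness occupational,10011893
Deafness permanent,10011894
Deafness transitory,10011900
Deafness unilateral,10048812
Deafness,10011878
Diplacusis,10013032
Dysacusis,10049712
Electrocochleogram abnormal,10014399
Eustachian tube disorder,10061462
Eustachian tube dysfunction,10015543
Eustachian tube obstruction,10015544
Haematotympanum,10063013
Hearing aid therapy,10075385
Hearing therapy,10087034
Hyperacusis,10020559
Hypoacusis,10048865
Middle ear adhesions,10027582
Middle ear effusion,10062545
Middle ear inflammation,10065838
Misophonia,10079388
Mixed deafness,10027757
Myringitis,10061302
Neonatal deafness,10080897
Neonatal hypoacusis,10080902
Neurosensory hypoacusis,10067587
Noninfective myringitis,10078830
Ossicle disorder,10061327
Otoacoustic emissions test abnormal,10063643
Otosalpingitis,10033102
Otosclerosis,10033103
Ototoxicity,10033109
Paracusis,10085733
Presbyacusis,10036626
Rinne tuning fork test abnormal,10039191
Sudden hearing loss,10061373
Tinnitus retraining therapy,10084652
Tinnitus,10043882
Tympanic membrane atrophic,10045208
Tympanic membrane disorder,10062218
Tympanic membrane perforation,10045210
Tympanic membrane scarring,10063604
Tympanometry abnormal,10045215
Tympanosclerosis,10045218
Weber tuning fork test abnormal,10047878
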