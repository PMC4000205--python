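study_id,model_id,disease_category,medical_question,platform_color,n_train,imbalance,cv_technique,gene_selection,classifier_class,n_genes_final,accuracy,n_eval,n_correct,n_incorrect
S001,S001m1,other,diagnostic,two-color,44,0.7727272727272727,single,wrapper,non-interaction,117,0.8636363636363636,44,38,6
S001,S001m2,other,diagnostic,two-color,44,0.7727272727272727,nested,filter,interaction,22,0.7954545454545454,44,35,9
S001,S001m3,other,diagnostic,two-color,44,0.7727272727272727,nested,embedded,interaction,76,0.7954545454545454,44,35,9
S001,S001m4,other,diagnostic,two-color,44,0.7727272727272727,nested,embedded,non-interaction,75,0.8181818181818182,44,36,8
S002,S002m1,mental disorder,diagnostic,one-color,65,0.7230769230769231,single,wrapper,interaction,149,0.8769230769230769,65,57,8
S002,S002m2,mental disorder,diagnostic,one-color,65,0.7230769230769231,nested,filter,interaction,46,0.8153846153846154,65,53,12
S002,S002m3,mental disorder,diagnostic,one-color,65,0.7230769230769231,nested,embedded,non-interaction,10,0.8153846153846154,65,53,12
S003,S003m1,inflammatory disorder,diagnostic,one-color,49,0.6530612244897959,nested,wrapper,interaction,41,0.8367346938775511,49,41,8
S003,S003m2,inflammatory disorder,diagnostic,one-color,49,0.6530612244897959,single,embedded,non-interaction,73,0.8979591836734694,49,44,5
S004,S004m1,infection,diagnostic,one-color,30,0.6333333333333333,nested,filter,interaction,156,0.8333333333333334,30,25,5
S004,S004m2,infection,diagnostic,one-color,30,0.6333333333333333,nested,wrapper,interaction,55,0.8333333333333334,30,25,5
S005,S005m1,immune disease,diagnostic,two-color,69,0.8695652173913043,nested,embedded,non-interaction,142,0.8405797101449275,69,58,11
S005,S005m2,immune disease,diagnostic,two-color,69,0.8695652173913043,single,filter,interaction,109,0.9130434782608695,69,63,6
S006,S006m1,degenerative disease,diagnostic,one-color,67,0.8805970149253731,nested,wrapper,non-interaction,40,0.8507462686567164,67,57,10
S007,S007m1,inflammatory disorder,diagnostic,one-color,43,0.627906976744186,nested,embedded,interaction,83,0.8604651162790697,43,37,6
S008,S008m1,infection,diagnostic,one-color,25,0.88,single,embedded,interaction,18,0.92,25,23,2
S009,S009m1,inflammatory disorder,diagnostic,two-color,68,0.8382352941176471,nested,wrapper,non-interaction,158,0.8529411764705882,68,58,10
S010,S010m1,infection,diagnostic,one-color,41,0.7804878048780488,nested,filter,interaction,113,0.8536585365853658,41,35,6
S011,S011m1,degenerative disease,diagnostic,one-color,37,0.6756756756756757,nested,embedded,non-interaction,68,0.8648648648648649,37,32,5
S012,S012m1,inflammatory disorder,diagnostic,one-color,38,0.631578947368421,single,wrapper,interaction,84,0.9473684210526315,38,36,2
S013,S013m1,mental disorder,diagnostic,two-color,51,0.8235294117647058,nested,filter,interaction,150,0.8823529411764706,51,45,6
S014,S014m1,immune disease,diagnostic,one-color,54,0.8518518518518519,nested,embedded,non-interaction,23,0.8888888888888888,54,48,6
S015,S015m1,inflammatory disorder,diagnostic,one-color,64,0.546875,nested,wrapper,interaction,127,0.890625,64,57,7
S016,S016m1,infection,diagnostic,two-color,30,0.6,single,embedded,non-interaction,112,0.9666666666666667,30,29,1
S017,S017m1,inflammatory disorder,diagnostic,one-color,81,0.5679012345679012,nested,filter,interaction,129,0.8888888888888888,81,72,9
S018,S018m1,other,diagnostic,one-color,33,0.6363636363636364,nested,wrapper,interaction,69,0.9090909090909091,33,30,3
S019,S019m1,infection,diagnostic,one-color,75,0.7466666666666667,single,embedded,non-interaction,111,0.9733333333333334,75,73,2
S020,S020m1,degenerative disease,diagnostic,two-color,74,0.7027027027027027,nested,filter,interaction,155,0.9054054054054054,74,67,7
S021,S021m1,inflammatory disorder,diagnostic,one-color,68,0.6764705882352942,nested,embedded,non-interaction,147,0.9117647058823529,68,62,6
S022,S022m1,mental disorder,diagnostic,one-color,45,0.5333333333333333,nested,wrapper,interaction,146,0.9111111111111111,45,41,4
S023,S023m1,immune disease,diagnostic,one-color,55,0.6,single,embedded,interaction,6,0.9818181818181818,55,54,1
S024,S024m1,inflammatory disorder,diagnostic,two-color,63,0.6190476190476191,nested,wrapper,non-interaction,64,0.9206349206349206,63,58,5
S025,S025m1,infection,diagnostic,one-color,38,0.631578947368421,nested,filter,interaction,54,0.9210526315789473,38,35,3
S026,S026m1,inflammatory disorder,diagnostic,one-color,32,0.84375,nested,embedded,interaction,152,0.9375,32,30,2
S027,S027m1,infection,diagnostic,two-color,24,0.5416666666666666,single,wrapper,non-interaction,63,1.0,24,24,0
S028,S028m1,degenerative disease,diagnostic,one-color,26,0.7692307692307693,nested,embedded,interaction,32,0.9230769230769231,26,24,2
S029,S029m1,inflammatory disorder,diagnostic,one-color,69,0.7971014492753623,nested,filter,non-interaction,110,0.9420289855072463,69,65,4
S030,S030m1,infection,prognostic,one-color,67,0.8507462686567164,single,wrapper,interaction,55,0.835820895522388,67,56,11
S030,S030m2,infection,prognostic,one-color,67,0.8507462686567164,nested,embedded,interaction,79,0.835820895522388,67,56,11
S031,S031m1,inflammatory disorder,prognostic,two-color,24,0.7083333333333334,single,filter,non-interaction,121,0.875,24,21,3
S032,S032m1,mental disorder,prognostic,one-color,79,0.8860759493670886,single,embedded,interaction,153,0.8987341772151899,79,71,8
S033,S033m1,immune disease,prognostic,one-color,36,0.75,nested,wrapper,non-interaction,34,0.9722222222222222,36,35,1
S034,S034m1,inflammatory disorder,prognostic,one-color,25,0.76,single,embedded,interaction,106,0.92,25,23,2
S035,S035m1,other,prognostic,two-color,59,0.6949152542372882,single,filter,interaction,59,0.9661016949152542,59,57,2
S036,S036m1,infection,response-to-treatment,one-color,55,0.7818181818181819,single,wrapper,non-interaction,7,0.7636363636363637,55,42,13
S036,S036m2,infection,response-to-treatment,one-color,55,0.7818181818181819,nested,embedded,interaction,110,0.6909090909090909,55,38,17
S036,S036m3,infection,response-to-treatment,one-color,55,0.7818181818181819,single,wrapper,non-interaction,114,0.7636363636363637,55,42,13
S037,S037m1,degenerative disease,response-to-treatment,one-color,35,0.8285714285714286,single,filter,interaction,121,0.7714285714285715,35,27,8
S037,S037m2,degenerative disease,response-to-treatment,one-color,35,0.8285714285714286,single,embedded,interaction,116,0.8,35,28,7
S038,S038m1,inflammatory disorder,response-to-treatment,two-color,62,0.7903225806451613,nested,wrapper,non-interaction,148,0.7419354838709677,62,46,16
S038,S038m2,inflammatory disorder,response-to-treatment,two-color,62,0.7903225806451613,single,embedded,interaction,23,0.8064516129032258,62,50,12
S039,S039m1,infection,response-to-treatment,one-color,46,0.6086956521739131,single,filter,non-interaction,19,0.8260869565217391,46,38,8
S040,S040m1,inflammatory disorder,response-to-treatment,one-color,64,0.71875,single,embedded,interaction,81,0.828125,64,53,11
S041,S041m1,mental disorder,response-to-treatment,one-color,44,0.75,nested,wrapper,interaction,86,0.7727272727272727,44,34,10
S042,S042m1,immune disease,response-to-treatment,two-color,50,0.74,single,filter,non-interaction,56,0.84,50,42,8
S043,S043m1,inflammatory disorder,response-to-treatment,one-color,55,0.8,single,embedded,interaction,9,0.8545454545454545,55,47,8
S044,S044m1,infection,response-to-treatment,one-color,32,0.59375,single,wrapper,non-interaction,151,0.875,32,28,4
S045,S045m1,degenerative disease,response-to-treatment,one-color,34,0.8823529411764706,nested,embedded,interaction,122,0.8235294117647058,34,28,6
S046,S046m1,inflammatory disorder,response-to-treatment,two-color,24,0.625,single,filter,interaction,60,0.875,24,21,3
S047,S047m1,infection,response-to-treatment,one-color,74,0.6891891891891891,single,wrapper,non-interaction,31,0.8918918918918919,74,66,8
S048,S048m1,inflammatory disorder,response-to-treatment,one-color,49,0.7959183673469388,single,embedded,interaction,103,0.8979591836734694,49,44,5
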