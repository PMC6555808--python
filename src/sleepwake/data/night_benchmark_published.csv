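method,group,accuracy,specificity,precision,sensitivity,f1,waso_min,mae_waso,sleep_eff_pct,mae_sleep_eff
Ground truth,oracle,100.0,100.0,100.0,100.0,100.0,102.1,0.0,58.4,0.0
Manual annotations,baseline,79.8,56.5,75.8,94.8,83.3,45.8,74.7,73.0,17.2
Device algorithm,baseline,76.2,50.1,72.6,94.3,81.3,54.0,53.1,75.7,17.7
Always sleep,baseline,58.4,0.0,58.4,100.0,72.8,0.0,102.1,100.0,41.6
Always wake,baseline,41.6,100.0,0.0,0.0,0.0,459.2,357.0,0.0,58.4
Oakley theta=10,traditional,77.5,63.0,76.8,87.2,81.0,95.0,37.3,66.0,10.1
Scripps Clinic,traditional,76.6,48.8,72.5,95.9,81.8,46.3,58.5,77.1,18.9
Oakley theta=40,traditional,75.9,49.3,72.2,94.4,81.2,53.1,52.9,76.0,17.9
Cole-Kripke,traditional,75.4,45.0,71.1,96.7,81.2,40.2,63.5,79.2,21.0
Sazonov,traditional,75.2,73.3,79.9,75.5,76.7,149.2,58.7,54.9,9.1
Oakley theta=80,traditional,73.9,41.2,69.7,96.9,80.3,35.9,67.4,80.9,22.7
Sadeh,traditional,73.4,38.3,69.1,98.3,80.3,26.3,76.5,83.0,24.7
Webster,traditional,73.3,38.2,69.0,98.2,80.3,27.5,75.3,83.0,24.7
Resc. Oakley theta=40,rescored_traditional,80.3,68.3,79.9,88.1,83.1,93.2,37.7,64.4,9.0
Resc. Cole-Kripke,rescored_traditional,80.2,65.7,78.9,89.9,83.3,83.5,40.0,66.6,10.2
Resc. Scripps Clinic,rescored_traditional,80.1,70.4,80.7,86.3,82.6,102.8,41.8,62.5,9.1
Resc. Oakley theta=80,rescored_traditional,79.3,59.8,76.6,92.8,83.2,65.0,46.4,70.7,13.1
Resc. Sadeh,rescored_traditional,79.1,59.4,76.5,92.8,83.1,64.1,49.2,70.9,13.5
Resc. Webster,rescored_traditional,79.0,58.9,76.2,93.1,83.0,63.2,48.9,71.3,13.8
Resc. Oakley theta=10,rescored_traditional,77.8,81.6,85.5,73.8,78.0,163.9,68.7,50.7,10.8
Resc. Sazonov,rescored_traditional,68.1,90.1,87.8,51.2,62.3,258.4,156.7,34.0,24.7
Extra trees,ml,81.8,68.1,80.3,90.4,84.3,85.4,42.8,65.8,10.3
Logistic regression,ml,81.5,67.2,79.9,90.7,84.1,83.2,45.6,66.3,11.1
Linear SVM,ml,81.4,68.0,80.2,89.9,83.8,87.2,45.8,65.5,10.8
Perceptron,ml,78.4,69.0,79.4,83.9,80.7,110.3,44.0,61.7,9.3
Resc. Logistic regression,rescored_ml,78.9,80.7,85.6,75.9,78.8,152.8,64.5,52.2,10.6
Resc. Extra trees,rescored_ml,78.5,82.0,86.1,74.2,78.2,160.4,68.6,50.8,11.0
Resc. Linear SVM,rescored_ml,78.3,81.4,85.8,74.4,77.9,159.4,69.6,51.1,11.2
Resc. Perceptron,rescored_ml,73.4,84.4,85.7,63.8,70.8,202.2,104.4,43.7,16.2
LSTM 100,dl,83.1,69.9,81.6,91.4,85.5,79.2,43.9,65.6,10.0
CNN 100,dl,82.9,68.8,81.3,91.7,85.3,78.3,46.7,66.2,10.8
LSTM 50,dl,82.7,70.1,81.5,90.5,85.0,85.6,41.3,64.9,9.6
CNN 50,dl,82.5,67.6,80.5,92.0,85.1,75.9,46.6,66.9,11.0
CNN 20,dl,81.4,66.5,79.6,90.9,84.1,81.9,43.2,66.7,10.8
LSTM 20,dl,81.3,65.0,79.0,92.0,84.3,75.3,44.5,68.0,11.4
Resc. LSTM 100,rescored_dl,81.2,77.8,84.8,82.1,82.3,123.4,47.2,57.1,8.7
Resc. CNN 100,rescored_dl,80.9,78.3,85.1,81.1,81.7,128.1,50.8,56.4,9.3
Resc. CNN 50,rescored_dl,80.6,78.2,84.8,80.6,81.4,130.0,51.4,56.1,9.3
Resc. LSTM 50,rescored_dl,79.9,80.1,85.6,78.0,80.4,142.9,55.6,53.8,9.5
Resc. LSTM 20,rescored_dl,79.5,79.9,85.2,77.5,79.9,145.2,56.9,53.6,9.6
Resc. CNN 20,rescored_dl,78.4,81.3,85.7,74.5,78.2,158.5,66.8,51.3,10.8
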